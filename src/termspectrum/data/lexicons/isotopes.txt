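# Stable isotopes, mass number followed by element symbol
1H
2H
3HE
4HE
6LI
7LI
9BE
10B
11B
12C
13C
14N
15N
16O
17O
18O
19F
20NE
21NE
22NE
23NA
24MG
25MG
26MG
27AL
28SI
29SI
30SI
31P
32S
33S
34S
36S
35CL
37CL
36AR
38AR
40AR
39K
41K
40CA
42CA
43CA
44CA
46CA
48CA
45SC
46TI
47TI
48TI
49TI
50TI
50V
51V
50CR
52CR
53CR
54CR
55MN
54FE
56FE
57FE
58FE
59CO
58NI
60NI
61NI
62NI
64NI
63CU
65CU
64ZN
66ZN
67ZN
68ZN
70ZN
69GA
71GA
70GE
72GE
73GE
74GE
76GE
75AS
74SE
76SE
77SE
78SE
80SE
82SE
79BR
81BR
78KR
80KR
82KR
83KR
84KR
86KR
85RB
87RB
84SR
86SR
87SR
88SR
89Y
90ZR
91ZR
92ZR
94ZR
96ZR
93NB
92MO
94MO
95MO
96MO
97MO
98MO
100MO
96RU
98RU
99RU
100RU
101RU
102RU
104RU
103RH
102PD
104PD
105PD
106PD
108PD
110PD
107AG
109AG
106CD
108CD
110CD
111CD
112CD
113CD
114CD
116CD
113IN
115IN
112SN
114SN
115SN
116SN
117SN
118SN
119SN
120SN
122SN
124SN
121SB
123SB
120TE
122TE
123TE
124TE
125TE
126TE
128TE
130TE
127I
129XE
131XE
132XE
134XE
136XE
133CS
130BA
132BA
134BA
135BA
136BA
137BA
138BA
139LA
195PT
197AU
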