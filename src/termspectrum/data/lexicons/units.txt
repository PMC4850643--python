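# Measurement unit strings; matching is by (case-insensitive) suffix,
# so entries must be long enough not to clip ordinary word endings.
ppm
ppb
mol
mmol
kv
mv
ev
(ev)
a.u
(a.u.)
°c
gcat
gcat h
mol-1
mol%
min-1
h-1
g-1
s-1
l-1
ml-1
cm-1
nm-1
kj
kcal
kpa
mpa
torr
mbar
khz
mhz
wt.%
vol.%
g/h
ml/min
cm3/min
m2/g
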