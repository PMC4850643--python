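# token	comp	oscar	expected	expected_id
SIZE(**)	0	-	rubbish	SpecialSymbolsRule
SELECTIVITY%	0	-	rubbish	SpecialSymbolsRule
NIMG_650	0	-	rubbish	SpecialSymbolsRule
H2S↔35SCAT	0	-	rubbish	SpecialSymbolsRule
1AUDAE_AM	0	-	rubbish	SpecialSymbolsRule
ΔGADS	0	-	rubbish	SpecialSymbolsRule
H0 ≦-8.22	0	-	rubbish	SpecialSymbolsRule
15 %H3PW12O40/TIO2	0	-	rubbish	SpecialSymbolsRule
LITERATURE	0	-	rubbish	StopListRule
VIEWPOINT	0	-	rubbish	StopListRule
PERCENT	0	-	rubbish	StopListRule
PRESENT	0	-	rubbish	StopListRule
IMPORTANCE	0	-	rubbish	StopListRule
FUNDAMENTAL	0	-	rubbish	StopListRule
CONCLUSION	0	-	rubbish	StopListRule
TYPICALLY	0	-	rubbish	StopListRule
EXAMPLE	0	-	rubbish	StopListRule
INTRODUCTION	0	-	rubbish	StopListRule
FQM-3994	0	-	rubbish	4DigitRule
RYC-2008-03387	0	-	rubbish	4DigitRule
20000H-1	0	-	rubbish	4DigitRule
MAT2010-21147	0	-	rubbish	4DigitRule
215KMTA	0	-	rubbish	3DigitRule
220ML	0	-	rubbish	3DigitRule
148H-1	0	-	rubbish	3DigitRule
31P{1H}	0	-	rubbish	2DigitRule
2-PROPANOL	0	-	rubbish	2DigitRule
2-METHYL-1-BUTENE	0	-	rubbish	2DigitRule
3-METHYL-1,3-BUTADIENE	0	-	rubbish	2DigitRule
KJMOL-1	0	-	rubbish	UnitsRule
MMOL.MIN-1	0	-	rubbish	UnitsRule
KJ.MOL-1	0	-	rubbish	UnitsRule
G.GZEOLITE-1.H-1	0	-	rubbish	UnitsRule
CM3.MIN-1.G-1	0	-	rubbish	UnitsRule
RU(0001)	0	-	valid	facet_index_4digits
CO(0001)-CARBIDE	0	-	valid	facet_index_4digits
α-FE2O3(0001)	0	-	valid	facet_index_4digits
CO(111)/CO(0001)	0	-	valid	facet_index_4digits
RU(0001) ELECTRODE	0	-	valid	facet_index_4digits
CEO2(111)	0	-	valid	miller_index_3digits
PT(111)	0	-	valid	miller_index_3digits
AU{111}-CEO2{100}	0	-	valid	miller_index_3digits
(NI,AL)(111)	0	-	valid	miller_index_3digits
AL2O3/NIAL(110)	0	-	valid	miller_index_3digits
CU2O(111)	0	-	valid	miller_index_3digits
MGO/AG(100)	0	-	valid	miller_index_3digits
15N218O	0	-	valid	substances_3digits
H235S	0	-	valid	substances_3digits
H218O-SSITKA	0	-	valid	substances_3digits
H216O/H218O	0	-	valid	substances_3digits
13C	0	-	valid	isotopes
12C16O-13C16O	0	-	valid	isotopes
31P	0	-	valid	isotopes
5-PENTANEDIOL	0	-	valid	substances_2digits
2-AMINOBENZENE-1,4-DICARBOXYLATE	0	-	valid	substances_2digits
5-BROMO-3-(N,N-DIETHYLAMINO-ETHOXY)-2-METHYLINDOLE	0	-	valid	substances_2digits
1.5AU/C	0	-	valid	catalysts
1.0CUCOK/ZRO2	0	-	valid	catalysts
CE0.9PR0.1O2	0	-	valid	catalysts
CU0.2CO0.8FE2O4	0	-	valid	catalysts
MG3ZN3.-XFE0.5AL0.5	0	-	valid	catalysts
LAFE0.7NI0.3O3-Δ	0	-	valid	catalysts
CE0.8GD0.2O2-Δ	0	-	valid	catalysts
MN0.8ZR0.2	0	-	valid	catalysts
20 %CU/ZNAL	1	-	valid	comp
0.4 %PD/AL2O3	1	-	valid	comp
4 %PT-4 %RE/TIO2	1	-	valid	comp
(5 %)PB(10 %)-SBA15	1	-	valid	comp
AL(NO3)3*6H2O	0	-	valid	cryst_hydrates
FE2(SO4)3.9H2O	0	-	valid	catalysts
AUCL4(NH4)7[TI2(O2)2(CIT)(HCIT)]2.12H2O	0	-	valid	catalysts
2D-SAXS	0	-	valid	spatial_dimension
2D-GC	0	-	valid	spatial_dimension
1D-3D COPPER - OXIDE	0	-	valid	spatial_dimension
1D-STRUCTURE	0	-	valid	spatial_dimension
1D COPPER - OXIDE	0	-	valid	spatial_dimension
BRØNSTED	0	-	valid	names
MÖSSBAUER	0	-	valid	names
BRØNSTED ACID	0	-	valid	names
BRØNSTED BASIC SITE	0	-	valid	names
MÖSSBAUER SPECTROSCOPY	0	-	valid	names
STEM-HAADF	0	CM	valid	oscar_tags
L-CYSTINE	0	CM	valid	oscar_tags
DI-TERT-BUTYLPEROXIDE	0	CM	valid	oscar_tags
[AU(EN)2]2[CU(OX)2]3	0	CM	valid	oscar_tags
HPG1800B	0	-	rubbish	4DigitRule
R873	0	-	rubbish	3DigitRule
50WX8-100	0	-	rubbish	3DigitRule
270-470OC3	0	-	rubbish	3DigitRule
FA100	0	-	rubbish	3DigitRule
TSVET-500	0	-	rubbish	3DigitRule
CE-4404	0	-	rubbish	4DigitRule
04,21H	0	-	rubbish	2DigitRule
11H	0	-	rubbish	2DigitRule
11HV	0	-	rubbish	2DigitRule
1 %18O2	0	-	rubbish	SpecialSymbolsRule
-1H-1	0	-	rubbish	UnitsRule
57CO5	0	-	rubbish	2DigitRule
2R,3S	0	-	rubbish	2DigitRule
2LFH	0	-	rubbish	2DigitRule
5NICZPOL	0	-	rubbish	2DigitRule
1KPM	0	-	rubbish	2DigitRule
4-CP6	0	-	rubbish	2DigitRule
VOL. %	0	-	rubbish	SpecialSymbolsRule
(B)2.5 %	0	-	rubbish	SpecialSymbolsRule
DISP.[%]7	0	-	rubbish	SpecialSymbolsRule
50 %AIR	0	-	rubbish	SpecialSymbolsRule
1.5 %WT	0	-	rubbish	SpecialSymbolsRule
0-2.5MOL %	0	-	rubbish	SpecialSymbolsRule
CA.23 %	0	-	rubbish	SpecialSymbolsRule
0.6 %H2O	0	-	rubbish	SpecialSymbolsRule
0.03 %C3H6	0	-	rubbish	SpecialSymbolsRule
0.06286*T	0	-	rubbish	SpecialSymbolsRule
12-MR	0	-	rubbish	2DigitRule
1LATTICE	0	-	rubbish	2DigitRule
16ACR	0	-	rubbish	2DigitRule
60HPW10	0	-	rubbish	2DigitRule
L'ARGENTIÈRE	0	-	rubbish	SpecialSymbolsRule
PROCESS'S	0	-	rubbish	SpecialSymbolsRule
128°- Y-ROTATED	0	-	rubbish	SpecialSymbolsRule
π- BACKDONATION	0	-	rubbish	SpecialSymbolsRule
CONVERSION(%)	0	-	rubbish	SpecialSymbolsRule
CATALYST	0	-	valid	-
HYDROGEN	0	-	valid	-
REACTION	0	-	valid	-
TEMPERATURE-PROGRAMMED	0	-	valid	-
H2O	0	-	valid	-
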