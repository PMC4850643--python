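# phrase	pos	oscar	comp	has_rubbish	expected	expected_rule
barium	NNP	CM	0	0	accept	ChemUnigramRule
phenanthrene	NNP	CM	0	0	accept	ChemUnigramRule
pentanol	NNP	CM	0	0	accept	ChemUnigramRule
xanes	NNP	CM	0	0	accept	ChemUnigramRule
2.7 %CO/10.0 %H2O/He	CD	CM	1	0	accept	ChemUnigramRule
hydrocalcite	NN	-	0	0	accept	default_accept
acetylacetone	NN	-	0	0	accept	default_accept
ethylene	NN	-	0	0	accept	default_accept
sulfamethoxazole	NN	-	0	0	accept	default_accept
12n-decylhexadecanamide	NN	-	0	0	accept	default_accept
cracking	VBG	-	0	0	accept	default_accept
ageing	VBG	-	0	0	accept	default_accept
leaching	VBG	-	0	0	accept	default_accept
anchoring	VBG	-	0	0	accept	default_accept
decomposition	NN	-	0	0	accept	GeneralChemTermRule
selectivity	NN	-	0	1	accept	GeneralChemTermRule
VIEWPOINT	NN	-	0	1	reject	StrictFilteringTagRule
topography	NN	-	0	0	reject	GeneralEnglishDictRule
paint	NN	-	0	0	reject	GeneralEnglishDictRule
plateau	NN	-	0	0	reject	GeneralEnglishDictRule
pool	NN	-	0	0	reject	GeneralEnglishDictRule
file	NN	-	0	0	reject	GeneralEnglishDictRule
addenda	NN	-	0	0	reject	GeneralEnglishDictRule
improvement	NN	-	0	0	reject	GeneralEnglishDictRule
theme	NN	-	0	0	reject	GeneralEnglishDictRule
searching	VBG	-	0	0	reject	GeneralEnglishDictRule
schematized	VBN	-	0	0	reject	UnigramPOSRule
suddenly	RB	-	0	0	reject	GeneralEnglishDictRule
skeletal	JJ	-	0	0	reject	UnigramPOSRule
behind	IN	-	0	0	reject	GeneralEnglishDictRule
AA	NN	-	0	0	reject	ShortTokensRule
KJMOL-1	NN	-	0	0	reject	UnitsRule
M(O2)	NN	-	0	0	reject	UnigramAddRules
GA15.6	NN	-	0	0	reject	UnigramAddRules
PW91	NN	-	0	0	reject	UnigramAddRules
V2.1	NN	-	0	0	reject	UnigramAddRules
G(D)	NN	-	0	0	reject	UnigramAddRules
TI(V)	NN	-	0	0	reject	UnigramAddRules
PD(I)	NN	-	0	0	reject	UnigramAddRules
PT0	NN	-	0	0	reject	UnigramAddRules
P(X)	NN	-	0	0	reject	UnigramAddRules
BA2+	NN	-	0	0	reject	UnigramAddRules
CE(3+)	NN	-	0	0	reject	UnigramAddRules
cm3	NN	-	0	0	reject	UnigramAddRules
CH3	NN	-	0	0	reject	UnigramAddRules
Cu2+	NN	-	0	0	reject	UnigramAddRules
Mo6+	NN	-	0	0	reject	UnigramAddRules
Et-CP	NN	-	0	0	reject	UnigramAddRules
GC-MS	NN	-	0	0	reject	UnigramAddRules
Zn-Al	NN	-	0	0	reject	UnigramAddRules
Andronov|bifurcation	NNP,NN	-,-	0	0	accept	BiGramPOSRule
Na2CO3|impregnation	NNP,NN	-,-	0	0	accept	BiGramPOSRule
nickel|catalyst	NN,NN	-,-	0	0	accept	BiGramPOSRule
supported|MgO	VBN,NNP	-,-	0	0	accept	BiGramPOSRule
anchored|lysine	VBN,NN	-,-	0	0	accept	BiGramPOSRule
carbonaceous|particle	JJ,NN	-,-	0	0	accept	BiGramPOSRule
temperature-programmed|adsorption	JJ,NN	-,-	0	0	accept	BiGramPOSRule
Fischer-Tropsch|catalyst	NNP,NN	-,-	0	0	accept	BiGramPOSRule
UV-VIS|spectroscopy	NNP,NN	-,-	0	0	accept	BiGramPOSRule
Raman|spectroscopy	NNP,NN	-,-	0	0	accept	BiGramPOSRule
propagating|thermosynthesis	VBG,NN	-,-	0	0	accept	BiGramPOSRule
stirred|glass	VBN,NN	-,ONT	0	0	accept	BiGramPOSRule
concentration|gradient	NN,NN	-,-	0	0	accept	GeneralChemTermRule
involving|reforming	VBG,VBG	-,-	0	0	reject	BiGramPOSRule
reforming|minimizing	VBG,VBG	-,-	0	0	reject	BiGramPOSRule
using|in	VBG,IN	-,-	0	0	reject	BiGramPOSRule
Shimada|etc	NNP,FW	-,-	0	0	reject	BiGramPOSRule
catalyst|catalyst	NN,NN	-,-	0	0	reject	IdenticalTokensRule
PPM|C7H14	NN,NNP	-,-	0	0	reject	UnitsRule
70ML|MIN-1	NNP,NNP	-,-	0	0	reject	UnitsRule
CM3MIN-1|H2	NNP,NNP	-,-	0	0	reject	UnitsRule
MIN-1|FLOW	NNP,NN	-,-	0	0	reject	UnitsRule
H-1|GAS	NNP,NN	-,-	0	0	reject	UnitsRule
PPM|N2O/AR	NN,NNP	-,-	0	0	reject	UnitsRule
ML|G-1MIN-1	NNP,NNP	-,-	0	0	reject	UnitsRule
MOL-1|HYDROLYSIS	NNP,NN	-,-	0	0	reject	UnitsRule
PPM|NOX/5%O2/N2	NN,NNP	-,-	0	0	reject	UnitsRule
X-ray|fluorescence|spectrometer	NNP,NN,NN	-,-,-	0	0	accept	ManyGramPOSRule
Brønsted|basic|site	NNP,JJ,NN	-,-,-	0	0	accept	ManyGramPOSRule
Pd(110)|surface|oscillation	NNP,NN,NN	-,-,-	0	0	accept	ManyGramPOSRule
doping|CsPW|with|platinum	VBG,NNP,IN,NN	-,-,-,-	0	0	accept	ManyGramPOSRule
catalyzed|N2O|decomposition	VBN,NNP,NN	-,-,-	0	0	accept	ManyGramPOSRule
crystalline|phase|transition	JJ,NN,NN	-,-,-	0	0	accept	ManyGramPOSRule
catalyzed|oxidation|of|NO	JJ,NN,IN,NNP	-,-,-,-	0	0	accept	ManyGramPOSRule
complete|photoreduction|of|Pd(II)	JJ,NN,IN,NNP	-,-,-,-	0	0	accept	ManyGramPOSRule
reforming|of|the|biomass	NN,IN,DT,NN	-,-,-,-	0	0	accept	ManyGramPOSRule
drying|inside|the|microscope|column	VBG,RB,DT,NN,NN	-,-,-,-,-	0	0	accept	ManyGramPOSRule
in|situ|EXAF	FW,FW,NNP	-,-,-	0	0	accept	ManyGramPOSRule
toluene|adsorption|capacity	NN,NN,NN	-,-,-	0	0	accept	ManyGramPOSRule
cobalt|acetate|decomposition	NN,NN,NN	CM,CM,-	0	0	accept	ManyGramPOSRule
radial|concentration|gradient	JJ,NN,NN	-,-,-	0	0	accept	GeneralChemTermRule
content|catalytic|activity	NN,JJ,NN	-,-,-	0	0	accept	GeneralChemTermRule
used|during|steam|reforming	VBN,IN,NN,VBG	-,-,-,-	0	0	reject	ManyGramPOSRule
catalyzed|by|metalloporphyrin	VBN,IN,NN	-,-,-	0	0	reject	ManyGramPOSRule
investigated|by|XRD	VBN,IN,NNP	-,-,-	0	0	reject	ManyGramPOSRule
using|atomic|absorption	VBG,JJ,NN	-,-,-	0	0	reject	ManyGramPOSRule
oxide|oxide|layer	NN,NN,NN	-,-,-	0	0	reject	IdenticalTokensRule
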