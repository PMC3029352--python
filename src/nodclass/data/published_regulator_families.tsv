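family	induced_genes
basic helix-loop-helix (bHLH)	13
bZIP	7
CCAAT-binding TF	5
CCR4-NOT	3
DNA-binding protein-like	3
ERF/AP2	24
G2-like	1
GRAS	6
HB	9
HSF	2
KH	1
LIM domain-containing protein	1
LOB domain protein	1
MADS box	1
TFIIS	1
Myb	18
no apical meristem (NAM)	12
ovate protein family	1
RWP-RK domain protein	1
S1FA	1
SAR DNA-binding protein	1
TFIIS containing protein	1
WRKY	24
Zinc finger (Ran-binding)	1
Zinc finger, AN1-like	4
Zinc finger, B-box type	3
Zinc finger, C2H2 type	10
Zinc finger, CCCH-type	7
Zinc finger, CCHC-type	1
Zinc finger, DHHC type	1
Zinc finger, Dof-type	1
Zinc finger, FYVE/PHD-type	1
Zinc finger, GRF-type	1
Zinc finger, RING-type	23
Zinc finger, TAZ-type	2
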