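gene	log2fc
BMP2	1.75
BMPR2	1.05
SMAD4	0.49
ID1	1.18
NODAL	0.31
EP300	0.61
FOXC1	2.54
WNT3	0.62
FZD3	0.94
FRAT2	0.57
AXIN2	0.41
LEF1	1.08
FGF2	0.81
FGFR3	2.03
RRAS	-0.46
ZIC2	0.99
GLI2	0.65
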