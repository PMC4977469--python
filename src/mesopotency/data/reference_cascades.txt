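# Five mesoderm-inducing signaling cascades (feeder vs replated comparison)
BMP: BMP2 -> BMPR2 -> SMAD4 -> ID1 => Mesoderm Induction
NODAL: NODAL -> SMAD4 -> EP300 -> FOXC1 => Mesoderm Induction
WNT: WNT3 -> FZD3 -> FRAT2 -> AXIN2 -> LEF1 -> FOXC1 => Mesoderm Induction
FGF: FGF2 -> FGFR3 -> RRAS -> FOXC1 => Mesoderm Induction
Hedgehog: ZIC2 -> GLI2 -> FOXC1 => Mesoderm Induction
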