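# name	recognition	cut_offset_top	cut_offset_bottom
# cut_offset_top: bases 5' of the first recognition base at which the top
# strand cleaves (0 = immediately before the first base; negative = inside).
MaeIII	GTNAC	0	0
Tsp45I	GTSAC	0	0
EcoRI	GAATTC	-1	-1
HindIII	AAGCTT	-1	-1
BamHI	GGATCC	-1	-1
DdeI	CTNAG	-1	-1
HinfI	GANTC	-1	-1
TaqI	TCGA	-1	-1
RsaI	GTAC	-2	-2
AluI	AGCT	-2	-2
NlaIII	CATG	-4	-4
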