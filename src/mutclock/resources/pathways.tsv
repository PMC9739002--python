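pathway	gene
Cell cycle	CDKN2A
Cell cycle	CCND1
Cell cycle	CDK4
Cell cycle	RB1
Hippo	NF2
Hippo	FAT1
Hippo	LATS1
Hippo	LATS2
Myc	MYC
Myc	MYCN
Myc	MXD1
Notch	NOTCH1
Notch	NOTCH2
Notch	FBXW7
NRF2	NFE2L2
NRF2	KEAP1
NRF2	CUL3
PI3K	PIK3CA
PI3K	PTEN
PI3K	AKT1
PI3K	STK11
PI3K	TSC2
RTK/RAS	KRAS
RTK/RAS	EGFR
RTK/RAS	BRAF
RTK/RAS	NF1
RTK/RAS	ERBB2
RTK/RAS	RET
TGF-beta	SMAD4
TGF-beta	SMAD2
TGF-beta	TGFBR2
TGF-beta	ACVR2A
p53	TP53
p53	MDM2
p53	MDM4
p53	ATM
p53	CHEK2
Wnt	APC
Wnt	CTNNB1
Wnt	AXIN1
Wnt	AMER1
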