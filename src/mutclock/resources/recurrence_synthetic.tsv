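chrom	pos	ref	alt	gene	protein_change	count
12	25398284	C	T	KRAS	G12D	5000
12	25398284	C	A	KRAS	G12V	3500
7	140453136	A	T	BRAF	V600E	12000
3	178952085	A	G	PIK3CA	H1047R	3000
7	55249071	C	T	EGFR	T790M	600
6	152419923	A	G	ESR1	D538G	150
17	7577121	G	A	TP53	R273C	900
17	7578406	C	T	TP53	R175H	1200
10	43617416	T	C	RET	M918T	400
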