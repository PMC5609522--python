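# Conserved diagnostic residues per protein: dual NPA motifs (loops B and E),
# ar/R selectivity filter (H2, H5, LE1, LE2) and Froger's positions P1-P5.
# "*" marks a value left blank in the curated source table (missing).
gene	transcript_tag	NPA_LB	NPA_LE	H2	H5	LE1	LE2	P1	P2	P3	P4	P5
BvPIP1;1		NPA	NPA	F	H	T	R	Q	S	A	F	W
BvPIP1;2		NPA	NPA	F	H	T	R	Q	S	A	*	*
BvPIP1;3		NPA	NPA	F	H	T	R	Q	S	A	F	W
BvPIP2;1		NPA	NPA	F	H	T	R	Q	S	A	F	W
BvPIP2;2		NPA	NPA	F	H	T	R	Q	S	A	F	W
BvPIP2;3		NPA	NPA	F	H	T	R	Q	S	A	F	W
BvPIP2;4		NPA	NPA	F	H	T	R	M	S	A	F	W
BvTIP1;1		NPA	NPA	H	I	A	V	T	S	A	Y	W
BvTIP1;2		NPA	NPA	H	I	A	V	T	S	A	Y	W
BvTIP1;3		NPA	NPA	H	I	A	V	T	S	A	Y	W
BvTIP2;1		NPA	NPA	H	I	G	R	T	S	A	Y	W
BvTIP2;2		NPA	NPA	H	I	G	R	T	S	A	Y	W
BvTIP3;1		NPA	NPA	H	I	A	R	T	A	A	Y	W
BvTIP4;1		NPA	NPA	H	I	A	R	T	S	A	Y	W
BvTIP5;1		NPA	NPA	N	V	G	Y	T	S	A	Y	W
BvNIP1;1		NPA	NPA	W	V	A	R	F	S	A	Y	L
BvNIP4;1		NPA	NPA	W	V	A	R	F	S	A	Y	I
BvNIP4;2		NPS	NPA	W	A	A	R	L	S	A	Y	I
BvNIP5;1		NPS	NPV	A	I	G	R	F	T	A	Y	M
BvNIP5;2		NPS	NPV	A	I	A	R	F	T	A	Y	M
BvNIP6;1		NPS	NPV	S	I	G	R	F	T	A	Y	F
BvNIP6;2		NPA	NPA	S	I	G	R	Y	T	A	Y	M
BvNIP6;3		NPA	NPA	S	I	A	R	Y	T	A	Y	L
BvNIP7;1		NPA	NPA	A	V	G	R	F	S	A	Y	F
BvSIP1;1	alpha	NPT	NPA	I	V	P	N	M	A	A	Y	W
BvSIP1;1	beta	NPT	NPA	V	V	P	N	M	A	A	Y	W
BvSIP2;1		NPL	NPA	S	N	G	S	F	V	A	Y	W
BvXIP1;1		NPT	NPA	V	S	A	R	F	C	A	F	W
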