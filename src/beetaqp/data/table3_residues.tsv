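# Observed SDP residues per protein, grouped under the substrate heading the
# protein was listed beneath. A protein may appear under several substrates
# with different residues (the nine positions differ per substrate class).
substrate	gene	SDP1	SDP2	SDP3	SDP4	SDP5	SDP6	SDP7	SDP8	SDP9
NH3	BvNIP1;1	F	H	F	T	A	D	L	E	T
boric_acid	BvPIP1;2	T	I	H	P	E	L	L	T	P
boric_acid	BvPIP1;3	T	I	H	P	E	L	L	T	P
boric_acid	BvNIP5;2	T	I	H	P	E	L	L	A	P
boric_acid	BvNIP6;1	T	I	H	P	E	L	L	A	P
boric_acid	BvXIP1;1	T	I	H	P	E	L	L	T	P
CO2	BvPIP1;2	V	M	C	A	I	D	W	H	W
CO2	BvPIP1;3	V	M	C	A	I	H	W	D	W
CO2	BvPIP2;1	I	M	C	A	V	K	W	D	W
H2O2	BvPIP2;1	A	G	V	F	I	H	F	V	P
H2O2	BvPIP2;2	A	G	V	F	I	H	F	V	P
H2O2	BvPIP2;3	A	G	V	F	I	H	F	V	P
H2O2	BvPIP2;4	A	G	V	F	I	H	F	V	P
H2O2	BvTIP1;1	S	A	L	A	I	H	Y	V	P
H2O2	BvTIP3;1	A	A	L	T	I	H	Y	V	P
H2O2	BvNIP4;2	S	A	L	L	I	L	Y	V	P
urea	BvPIP1;1	H	P	F	L	L	P	G	G	N
urea	BvPIP1;2	H	P	F	L	L	P	G	G	N
urea	BvPIP1;3	H	P	L	F	L	P	G	G	N
urea	BvPIP2;1	H	P	F	L	L	P	G	G	N
urea	BvPIP2;2	H	P	F	F	L	P	G	G	N
urea	BvPIP2;3	H	P	F	F	L	P	G	G	N
urea	BvPIP2;4	H	P	F	F	L	P	G	G	N
urea	BvTIP1;1	H	P	F	F	L	A	G	S	N
urea	BvTIP1;2	H	P	F	F	L	P	G	S	N
urea	BvTIP1;3	H	P	L	F	L	A	G	S	N
urea	BvTIP2;1	H	P	F	A	L	P	G	S	N
urea	BvTIP2;2	H	P	F	A	L	P	G	S	N
urea	BvTIP3;1	H	P	F	L	L	P	G	S	N
urea	BvTIP4;1	H	P	L	A	L	L	G	S	N
urea	BvNIP1;1	H	P	I	A	L	P	G	S	N
urea	BvNIP4;1	H	P	L	A	L	P	G	S	N
urea	BvNIP4;2	H	P	I	A	L	T	G	S	N
urea	BvNIP5;1	H	P	I	A	L	P	G	S	N
urea	BvNIP5;2	H	P	I	A	L	P	G	S	N
urea	BvNIP6;1	H	P	I	A	L	P	G	S	N
urea	BvNIP6;2	H	P	L	A	L	P	G	S	N
urea	BvNIP6;3	H	P	I	A	L	P	G	S	N
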