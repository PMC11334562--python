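scheme	residue	class
exchange	H	1
exchange	R	1
exchange	K	1
exchange	D	2
exchange	E	2
exchange	N	2
exchange	Q	2
exchange	C	3
exchange	S	4
exchange	T	4
exchange	P	4
exchange	A	4
exchange	G	4
exchange	M	5
exchange	I	5
exchange	L	5
exchange	V	5
exchange	F	6
exchange	Y	6
exchange	W	6
electron	D	1
electron	E	1
electron	P	1
electron	A	1
electron	I	2
electron	L	2
electron	V	2
electron	K	3
electron	N	3
electron	R	3
electron	F	4
electron	Y	4
electron	M	4
electron	T	4
electron	Q	4
electron	G	5
electron	H	5
electron	W	5
electron	S	5
electron	C	6
r_group	G	1
r_group	A	1
r_group	V	1
r_group	L	1
r_group	M	1
r_group	I	1
r_group	F	2
r_group	Y	2
r_group	W	2
r_group	S	3
r_group	T	3
r_group	C	3
r_group	P	3
r_group	N	3
r_group	Q	3
r_group	K	4
r_group	R	4
r_group	H	4
r_group	D	5
r_group	E	5
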