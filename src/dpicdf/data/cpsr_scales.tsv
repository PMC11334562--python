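scale	residue	value
flexibility	A	0.984
flexibility	C	0.906
flexibility	D	1.068
flexibility	E	1.094
flexibility	F	0.915
flexibility	G	1.031
flexibility	H	0.950
flexibility	I	0.927
flexibility	K	1.102
flexibility	L	0.935
flexibility	M	0.952
flexibility	N	1.048
flexibility	P	1.049
flexibility	Q	1.037
flexibility	R	1.008
flexibility	S	1.046
flexibility	T	0.997
flexibility	V	0.931
flexibility	W	0.904
flexibility	Y	0.929
rigidity	A	1.016
rigidity	C	1.094
rigidity	D	0.932
rigidity	E	0.906
rigidity	F	1.085
rigidity	G	0.969
rigidity	H	1.050
rigidity	I	1.073
rigidity	K	0.898
rigidity	L	1.065
rigidity	M	1.048
rigidity	N	0.952
rigidity	P	0.951
rigidity	Q	0.963
rigidity	R	0.992
rigidity	S	0.954
rigidity	T	1.003
rigidity	V	1.069
rigidity	W	1.096
rigidity	Y	1.071
irreplaceability	A	1.000
irreplaceability	C	5.000
irreplaceability	D	0.943
irreplaceability	E	0.980
irreplaceability	F	2.439
irreplaceability	G	2.041
irreplaceability	H	1.515
irreplaceability	I	1.042
irreplaceability	K	1.786
irreplaceability	L	2.500
irreplaceability	M	1.064
irreplaceability	N	0.746
irreplaceability	P	1.786
irreplaceability	Q	1.075
irreplaceability	R	1.538
irreplaceability	S	0.833
irreplaceability	T	1.031
irreplaceability	V	1.351
irreplaceability	W	5.556
irreplaceability	Y	2.439
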