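residue_number	entropy	ligand_probability	ligand_confidence	Ec	Hi	Pa	Mc	Ef	Sp	Sa
116	0.747	0.687	0.211	K	K	K	K	K	K	K
131	1.917	0.802	0.452	V	V	V	V	V	V	V
157	2.003	0.710	0.373	I	I	I	I	M	I	I
159	0.763	0.733	0.403	K	K	K	K	K	K	K
163	2.153	0.304	0.159	G	G	G	G	G	G	G
164	1.289	0.463	0.202	G	G	G	G	G	G	G
165	0.659	0.553	0.318	G	G	G	G	G	G	G
166	0.020	0.599	0.355	G	G	G	G	G	G	G
169	1.861	0.456	0.195	M	M	M	M	I	I	I
201	1.941	0.870	0.567	E	E	E	E	E	E	E
202	2.096	0.869	0.419	K	K	K	R	K	R	K
203	2.183	0.864	0.457	Y	Y	F	F	I	V	F
204	1.939	0.874	0.660	L	L	L	L	I	I	I
233	1.130	0.368	0.139	Q	Q	Q	Q	Q	Q	Q
236	1.924	0.569	0.369	H	H	H	H	N	N	M
276	0.786	0.553	0.396	E	E	E	E	E	E	E
278	1.994	0.761	0.608	L	L	L	L	L	L	I
287	1.137	0.823	0.821	I	I	I	I	M	M	M
288	0.001	0.755	0.645	E	E	E	E	E	E	E
437	0.491	0.257	0.174	I	I	I	I	T	T	T
438	2.586	0.071	0.108	H	H	H	H	S	S	N
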