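contig	position	rsid	gene	ref	alt	classification	origin	gnomad_maf	gip_aaf
5	112792446	rs62619935	APC	C	T	Pathogenic	somatic	6.23E-07	NR
5	112815507	rs786201856	APC	C	A	VUS	somatic	NR	NR
5	112838397	rs1170472401	APC	T	C	Likely-benign	somatic	NR	NR
7	140753334	rs121913364	BRAF	T	G	Likely pathogenic	somatic	NR	NR
11	108247072	rs202160435	ATM	G	A	Conflicting pathogenicity	somatic	7.43E-05	0.000101307
17	7673803	rs121913343	TP53	G	A	Pathogenic	somatic	3.71E-06	NR
17	7675233	rs1597371694	TP53	A	T	VUS	somatic	NR	NR
17	7675989	rs1555526466	TP53	C	A	VUS	somatic	NR	NR
17	7676154	rs1042522	TP53	G	C	Benign	somatic	0.38	0.521759
17	7676230	rs1800371	TP53	G	C/A	VUS	somatic	NR	NR/0.000204666
18	51065435	rs2144446385	SMAD4	G	T	Pathogenic	somatic	NR	NR
22	28734532	rs141568342	CHK2	C	T	Pathogenic	somatic	1.75E-04	0.000460499
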