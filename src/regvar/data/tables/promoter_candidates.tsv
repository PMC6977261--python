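chrom	position	variant	alleles_p_r	raf	gene	aa_or_tf	marker	marker_p	study	r2	category
6	31371100	rs6906175	G/C	0.2952	MICA	REST	rs13437088	3.00E-40	[25]	1.0000	promoter
6	31430009	rs3132089	(G/A)?	NR	HCP5	ARNT,BHLHE40	rs3134792	1.00E-09	[18]	0.9253	promoter
6	31462134	rs3130923	(G/A)?	NR	MICB	TCF3	rs3134792	1.00E-09	[18]	0.8762	promoter
12	56728257	rs11358218	A/-	0.9304	PAN2	SPI1	rs2066807;rs2066808;rs2066819	5.00E-12;6.00E-10;5.00E-17	[27];[26];[25]	0.9541;1.0000;0.8933	promoter
16	30968588	rs4889599	C/T	0.3658	SETD1A	EGR1	rs10782001;rs12445568;rs13708	9.00E-10;1.00E-16;2.00E-08	[22];[25];[27]	0.9703;0.8876;0.9915	promoter
20	43989513	rs2741432	G/A	0.7744	SYS1	CEBPB	rs1008953	1.00E-07	[22]	0.9943	promoter
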