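chrom	position	variant	alleles_p_r	raf	gene	aa_or_tf	marker	marker_p	study	r2	category
6	31380000	rs199503730	G/-	0.0447	MICA	5'ss	rs2395029	2.00E-26	[19]	0.8860	splice
1	25291010	rs6672420	A/T	0.4791	RUNX3	I/N	rs7536201	2.00E-12;2.00E-08	[25];[29]	0.9046	exon
1	67705958	rs11209026	A/G	0.9384	IL23R	Q/R	rs11209026;rs9988642	7.00E-07;1.00E-26	[24];[25]	1.0000;0.8520	exon
6	31473957	rs3134900	(C/G)?	NR	MICB	I/M	rs3134792	1.00E-09	[18]	0.8008	exon
6	111913262	rs33980500	C/T	0.0855	TRAF3IP2	D/N	rs33980500	1.00E-16;4.00E-45;1.00E-23	[23];[25];[29]	1.0000	exon
17	78178893	rs11652075	T/C	0.5099	CARD14	W/R	rs11652075	3.00E-08	[25]	1.0000	exon
19	10463118	rs34536443	C/G	0.9712	TYK2	A/P	rs34536443	9.00E-31	[25]	1.0000	exon
19	10469975	rs12720356	C/A	0.9076	TYK2	S/I	rs12720356	4.00E-11	[25]	1.0000	exon
19	49206674	rs601338	G/A	0.4414	FUT2	W/*	rs492602	7.00E-13	[30]	0.9920	exon
19	49206985	rs602662	G/A	0.4682	FUT2	G/S	rs492602	7.00E-13	[30]	0.8822	exon
22	21982892	rs2298428	C/T	0.1769	YDJC	A/T	rs181359;rs4821124	2.00E-07;4.00E-08	[29];[25]	0.8941;0.9477	exon
5	96245518	rs2549797	G/A	0.5199	ERAP2	5'ss	rs2910686	2.00E-08	[25]	0.8051	splice
12	56660905	rs60542959	T/G	0.9344	COQ10A	I/M	rs2066807;rs2066808;rs2066819	5.00E-12;6.00E-10;5.00E-17	[27];[26];[25]	0.9523;0.9388;0.9517	exon
17	73874071	rs4600514	G/A	0.1650	TRIM47	R/W	rs55823223	1.00E-08	[30]	0.9075	exon
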