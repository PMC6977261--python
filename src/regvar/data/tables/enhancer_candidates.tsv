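chrom	position	variant	alleles_p_r	raf	gene	aa_or_tf	marker	marker_p	study	r2	category
1	8257959	rs72635708	T/C	0.2286	ERRFI1	ARNT,BACH1,FOS,MAFK,NFE2	rs417065	8.00E-07	[27]	0.9832	enhancer
11	64140624	rs11231770	A/G	0.6292	PPP1R14B	SP1,SP2,ZNF263	rs645078	2.00E-06	[25]	1.0000	enhancer
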