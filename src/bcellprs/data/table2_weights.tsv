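snp_id	risk_allele	other_allele	raf	or_sle	gene	in_bcell_prs	in_bcell_activation_prs	source
rs2230926	G	T	0.06	2.03	TNFAIP3	1	1	Morris et al
rs11073328	T	C	0.13	1.94	RASGRP1	1	0	Armstrong et al
rs8076347	T	C	0.05	1.93	IKZF3	1	1	Lessard et al
rs150518861	A	G	0.02	1.66	LAT2	1	1	Julia et al
rs7726414	T	C	0.05	1.45	SKP1	1	0	Bentham et al
rs4810485	T	G	0.26	1.43	CD40	1	1	Langefeld et al
rs13277113	A	G	0.32	1.39	BLK	1	0	Lee et al
rs6679677	A	C	0.15	1.39	PTPN22	1	0	Bentham et al
rs7829816	T	C	0.16	1.30	LYN	1	1	Harley et al
rs2286672	T	C	0.08	1.25	PSMB6	1	0	Bentham et al
rs9899849	A	G	0.26	1.21	GPS2	1	1	Wang et al
rs930297	A	G	0.09	1.20	GRB2	1	0	Langefeld et al
rs10028805	G	A	0.28	1.20	BANK1	1	1	Bentham et al
rs3024505	A	G	0.18	1.19	IL10	1	1	Gateva et al
rs597808	A	G	0.51	1.18	PTPN11	1	0	Bentham et al
rs1432296	T	C	0.19	1.18	REL	1	0	Langefeld et al
rs907715	G	A	0.31	1.16	IL21	1	1	Hughes et al
rs1966115	A	G	0.27	1.14	IL7	1	1	Langefeld et al
rs6871748	T	C	0.28	1.12	IL7R	1	1	Wang et al
rs3087243	G	A	0.38	1.12	CTLA4	1	1	Wang et al
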