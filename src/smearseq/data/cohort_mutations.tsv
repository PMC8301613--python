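patient	diagnosis	staining	elapsed_years	gene	hgvs_c	hgvs_p	vaf_percent
#097	AML	no	0.2	-	-	-	-
#112	AML	no	0.1	NRAS	c.181C>A	p.Gln61Lys	40.21
#220	t-AML	no	0.1	NRAS	c.182A>G	p.Gln61Arg	46.84
#226	AML	MGG	0.1	CEBPA	c.912_913insTTG	p.Lys304_Gln305insLeu	88.66
#226	AML	MGG	0.1	FLT3	c.1747_1794dup	ITD16aa	14.89
#152	AML-MRC	MGG	0.2	-	-	-	-
#111	AML	no	0.2	FLT3	c.1836_1837insCGGC1788_1836dup	ITD17aa	12.53
#161	AML	no	0.1	IDH1	c.395G>A	p.Arg132His	44.53
#175	AML	no	0.1	TP53	c.488A>G	p.Tyr163Cys	39.92
#176	AML	no	0.2	ASXL1	c.1605dupT	p.Pro536SerfsTer8	21.31
#176	AML	no	0.2	FLT3	c.2039C>T	p.Ala680Val	10.80
#232	AML	no	0.3	SRSF2	c.284C>A	p.Pro95His	51.47
#232	AML	no	0.3	NPM1	c.860_863dupTCTG	p.Trp288CysfsTer12	46.70
#256	AML	no	0.3	CEBPA	c.917_934delGCAACGTGGAGACGCAGC	p.Arg306_Gln311del	49.78
#256	AML	no	0.3	CEBPA	c.350dupG	p.Ala118ArgfsTer52	43.03
#256	AML	no	0.3	WT1	c.1223T>A	p.Leu408Ter	83.64
#256	AML	no	0.3	GATA2	c.949A>G	p.Asn317Asp	44.52
#191	AML	no	0.3	NRAS	c.34G>A	p.Gly12Ser	37.97
#191	AML	no	0.3	TET2	c.4144delC	p.His1382ThrfsTer66	46.88
#191	AML	no	0.3	TET2	c.1842dupG	p.Leu615AlafsTer23	38.29
#191	AML	no	0.3	NPM1	c.863_864insCATG	p.Trp288CysfsTer12	44.12
#191	AML	no	0.3	PTEN	c.802-2A>T	Splicing	5.51
#205	AML	MGG	1	SRSF2	c.284_307del	p.Pro95_Arg102del	45.87
#205	AML	MGG	1	IDH2	c.419G>A	p.Arg140Gln	33.72
#205	AML	MGG	1	STAG2	c.1810C>T	p.Arg604Ter	27.27
#205	AML	MGG	1	STAG2	c.2534-1G>A	Splicing	6.69
#153	AML-MRC	MGG	0.1	DDX41	c.1496dupC	p.Ala500CysfsTer9	48.83
#153	AML-MRC	MGG	0.1	DDX41	c.1574G>A	p.Arg525His	12.16
#153	AML-MRC	MGG	0.1	SRSF2	c.284C>G	p.Pro95Arg	11.69
#188	aCML	MGG	1	KRAS	c.35G>T	p.Gly12Val	37.97
#101	MDS	MGG	0.3	U2AF1	c.101C>T	p.Ser34Phe	31.77
#113	MDS	MGG	11	ATM	c.3078delG	p.Trp1026CysfsTer3	6.09
#233	MDS	MGG	0.1	TP53	c.659A>G	p.Tyr220Cys	18.65
#233	MDS	MGG	0.1	TP53	c.586C>T	p.Arg196Ter	15.30
#119	MDS	no	0.4	RUNX1	c.417C>A	p.Asn139Lys	48.05
#119	MDS	no	0.4	RUNX1	c.610C>T	p.Arg204Ter	29.65
#119	MDS	no	0.4	EZH2	c.458A>G	p.Tyr153Cys	40.73
#189	MDS	MGG	0.3	TP53	c.817C>T	p.Arg273Cys	17.34
#189	MDS	MGG	0.3	ASXL1	c.2350delG	p.Asp784MetfsTer34	3.04
#106	MDS	no	4	-	-	-	-
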