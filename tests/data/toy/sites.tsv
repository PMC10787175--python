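site_id	chrom	strand	coord	gene	region
A1	chr1	+	1100	geneA	intron
A2	chr1	+	1500	geneA	3UTR
B1	chr1	+	2100	geneB	intron
B2	chr1	+	2500	geneB	3UTR
C1	chr1	+	3100	geneC	3UTR
C2	chr1	+	3500	geneC	3UTR
D1	chr1	+	4100	geneD	intron
D2	chr1	+	4300	geneD	intron
D3	chr1	+	4500	geneD	3UTR
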