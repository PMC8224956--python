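##fileformat=VCFv4.2
##source=hand-built founder-filter fixture (synthetic)
##contig=<ID=scaffold_A,length=50000>
##contig=<ID=scaffold_small,length=3000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	founder	g1
scaffold_A	100	.	A	T	.	PASS	.	GT:AD:DP:GQ	0/1:15,15:30:40	0/0:20,0:20:60
scaffold_A	200	.	C	G	.	PASS	.	GT:AD:DP:GQ	0/1:20,30:50:99	0/1:10,10:20:50
scaffold_A	300	.	G	A	.	PASS	.	GT:AD:DP:GQ	0/1:18,12:30:35	1/1:0,25:25:70
scaffold_A	400	.	T	C	.	PASS	.	GT:AD:DP:GQ	0/1:40,41:81:80	0/0:30,0:30:80
scaffold_A	500	.	A	T,G	.	PASS	.	GT:AD:DP:GQ	0/1:10,10,10:30:50	0/0:18,0,0:18:45
scaffold_A	600	.	C	T	.	PASS	.	GT:AD:DP:GQ	0/0:30,0:30:90	0/1:12,13:25:55
scaffold_A	700	.	G	C	.	PASS	.	GT:AD:DP:GQ	./.:.:.:.	0/1:15,15:30:60
scaffold_A	800	.	T	A	.	PASS	.	GT:AD:DP:GQ	0/1:26,14:40:60	0/1:14,14:28:52
scaffold_A	900	.	A	C	.	PASS	.	GT:AD:DP:GQ	0/1:14,26:40:60	0/0:22,0:22:66
scaffold_A	1000	.	C	A	.	PASS	.	GT:AD:DP:GQ	0/1:14,15:29:50	0/1:16,14:30:58
scaffold_A	1100	.	G	T	.	PASS	.	GT:AD:DP:GQ	0/1:15,15:30:29	1/1:0,30:30:90
scaffold_small	100	.	T	G	.	PASS	.	GT:AD:DP:GQ	0/1:15,15:30:50	0/0:25,0:25:75
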