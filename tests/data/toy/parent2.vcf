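##fileformat=VCFv4.2
##source=binmapqtl_v0.1.0
##contig=<ID=Chr1>
##contig=<ID=Chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	Yugu1
Chr1	5413	.	A	G	.	PASS	.	GT	1/1
Chr1	49454	.	T	G	.	PASS	.	GT	1/1
Chr1	106579	.	C	T	.	PASS	.	GT	1/1
Chr1	169201	.	A	G	.	PASS	.	GT	1/1
Chr1	180477	.	A	T	.	PASS	.	GT	1/1
Chr1	237757	.	A	C	.	PASS	.	GT	1/1
Chr1	242546	.	A	G	.	PASS	.	GT	1/1
Chr1	347868	.	A	G	.	PASS	.	GT	1/1
Chr1	353611	.	C	T	.	PASS	.	GT	1/1
Chr1	379794	.	G	C	.	PASS	.	GT	1/1
Chr1	393366	.	G	C	.	PASS	.	GT	1/1
Chr1	393500	.	T	C	.	PASS	.	GT	1/1
Chr1	423658	.	A	C	.	PASS	.	GT	1/1
Chr1	428411	.	G	A	.	PASS	.	GT	1/1
Chr1	459622	.	A	T	.	PASS	.	GT	1/1
Chr1	461041	.	G	C	.	PASS	.	GT	1/1
Chr1	484341	.	G	A	.	PASS	.	GT	1/1
Chr1	503432	.	C	T	.	PASS	.	GT	1/1
Chr1	516998	.	G	C	.	PASS	.	GT	1/1
Chr1	590078	.	C	G	.	PASS	.	GT	1/1
Chr2	8399	.	G	T	.	PASS	.	GT	1/1
Chr2	21629	.	C	G	.	PASS	.	GT	1/1
Chr2	50272	.	C	A	.	PASS	.	GT	1/1
Chr2	70989	.	G	T	.	PASS	.	GT	1/1
Chr2	105416	.	C	G	.	PASS	.	GT	1/1
Chr2	124869	.	T	G	.	PASS	.	GT	1/1
Chr2	192912	.	A	C	.	PASS	.	GT	1/1
Chr2	227675	.	T	G	.	PASS	.	GT	1/1
Chr2	231703	.	A	C	.	PASS	.	GT	1/1
Chr2	245902	.	A	G	.	PASS	.	GT	1/1
Chr2	255975	.	T	G	.	PASS	.	GT	1/1
Chr2	263273	.	A	T	.	PASS	.	GT	1/1
Chr2	268299	.	G	T	.	PASS	.	GT	1/1
Chr2	295549	.	A	T	.	PASS	.	GT	1/1
Chr2	321251	.	C	G	.	PASS	.	GT	1/1
Chr2	349375	.	G	A	.	PASS	.	GT	1/1
Chr2	373142	.	C	A	.	PASS	.	GT	1/1
Chr2	392264	.	C	G	.	PASS	.	GT	1/1
Chr2	393832	.	G	T	.	PASS	.	GT	1/1
Chr2	456711	.	T	C	.	PASS	.	GT	1/1
Chr2	460317	.	C	G	.	PASS	.	GT	1/1
Chr2	465688	.	G	T	.	PASS	.	GT	1/1
Chr2	467415	.	T	C	.	PASS	.	GT	1/1
Chr2	470300	.	G	C	.	PASS	.	GT	1/1
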