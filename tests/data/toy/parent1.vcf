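##fileformat=VCFv4.2
##source=binmapqtl_v0.1.0
##contig=<ID=Chr1>
##contig=<ID=Chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	Longgu7
Chr1	2815	.	T	A	.	PASS	.	GT	1/1
Chr1	5413	.	A	G	.	PASS	.	GT	1/1
Chr1	16877	.	A	T	.	PASS	.	GT	1/1
Chr1	35117	.	G	T	.	PASS	.	GT	1/1
Chr1	41966	.	C	A	.	PASS	.	GT	1/1
Chr1	48363	.	T	C	.	PASS	.	GT	1/1
Chr1	69587	.	G	T	.	PASS	.	GT	1/1
Chr1	71702	.	G	C	.	PASS	.	GT	1/1
Chr1	100987	.	T	C	.	PASS	.	GT	1/1
Chr1	108439	.	C	G	.	PASS	.	GT	1/1
Chr1	109917	.	T	G	.	PASS	.	GT	1/1
Chr1	137316	.	T	G	.	PASS	.	GT	1/1
Chr1	141852	.	G	T	.	PASS	.	GT	1/1
Chr1	148195	.	T	G	.	PASS	.	GT	1/1
Chr1	148216	.	T	G	.	PASS	.	GT	1/1
Chr1	153178	.	G	A	.	PASS	.	GT	1/1
Chr1	164685	.	C	A	.	PASS	.	GT	1/1
Chr1	169201	.	A	G	.	PASS	.	GT	1/1
Chr1	180477	.	A	T	.	PASS	.	GT	1/1
Chr1	198978	.	A	T	.	PASS	.	GT	1/1
Chr1	237757	.	A	C	.	PASS	.	GT	1/1
Chr1	249529	.	A	T	.	PASS	.	GT	1/1
Chr1	266779	.	T	C	.	PASS	.	GT	1/1
Chr1	274508	.	C	G	.	PASS	.	GT	1/1
Chr1	286334	.	C	A	.	PASS	.	GT	1/1
Chr1	300548	.	T	A	.	PASS	.	GT	1/1
Chr1	349671	.	A	C	.	PASS	.	GT	1/1
Chr1	353611	.	C	T	.	PASS	.	GT	1/1
Chr1	365156	.	A	C	.	PASS	.	GT	1/1
Chr1	392096	.	A	T	.	PASS	.	GT	1/1
Chr1	398944	.	A	C	.	PASS	.	GT	1/1
Chr1	417427	.	T	G	.	PASS	.	GT	1/1
Chr1	459622	.	A	T	.	PASS	.	GT	1/1
Chr1	463843	.	T	G	.	PASS	.	GT	1/1
Chr1	465708	.	T	A	.	PASS	.	GT	1/1
Chr1	468293	.	G	A	.	PASS	.	GT	1/1
Chr1	476554	.	A	T	.	PASS	.	GT	1/1
Chr1	484239	.	C	A	.	PASS	.	GT	1/1
Chr1	484341	.	G	A	.	PASS	.	GT	1/1
Chr1	487232	.	T	C	.	PASS	.	GT	1/1
Chr1	498904	.	A	T	.	PASS	.	GT	1/1
Chr1	503432	.	C	T	.	PASS	.	GT	1/1
Chr1	515420	.	G	A	.	PASS	.	GT	1/1
Chr1	516998	.	G	C	.	PASS	.	GT	1/1
Chr1	533264	.	A	G	.	PASS	.	GT	1/1
Chr1	577540	.	C	G	.	PASS	.	GT	1/1
Chr1	596135	.	C	G	.	PASS	.	GT	1/1
Chr1	596497	.	G	A	.	PASS	.	GT	1/1
Chr1	597997	.	C	A	.	PASS	.	GT	1/1
Chr2	9551	.	C	G	.	PASS	.	GT	1/1
Chr2	13571	.	T	C	.	PASS	.	GT	1/1
Chr2	21629	.	C	G	.	PASS	.	GT	1/1
Chr2	29811	.	G	C	.	PASS	.	GT	1/1
Chr2	36248	.	G	C	.	PASS	.	GT	1/1
Chr2	50272	.	C	A	.	PASS	.	GT	1/1
Chr2	58207	.	C	G	.	PASS	.	GT	1/1
Chr2	59817	.	A	G	.	PASS	.	GT	1/1
Chr2	79836	.	T	G	.	PASS	.	GT	1/1
Chr2	80614	.	G	T	.	PASS	.	GT	1/1
Chr2	99809	.	C	G	.	PASS	.	GT	1/1
Chr2	105416	.	C	G	.	PASS	.	GT	1/1
Chr2	112525	.	G	A	.	PASS	.	GT	1/1
Chr2	137033	.	G	C	.	PASS	.	GT	1/1
Chr2	146733	.	A	T	.	PASS	.	GT	1/1
Chr2	156847	.	C	G	.	PASS	.	GT	1/1
Chr2	163164	.	C	G	.	PASS	.	GT	1/1
Chr2	173743	.	G	A	.	PASS	.	GT	1/1
Chr2	196374	.	T	G	.	PASS	.	GT	1/1
Chr2	215411	.	C	A	.	PASS	.	GT	1/1
Chr2	221006	.	T	C	.	PASS	.	GT	1/1
Chr2	231524	.	G	T	.	PASS	.	GT	1/1
Chr2	231703	.	A	C	.	PASS	.	GT	1/1
Chr2	240677	.	G	A	.	PASS	.	GT	1/1
Chr2	245902	.	A	G	.	PASS	.	GT	1/1
Chr2	255975	.	T	G	.	PASS	.	GT	1/1
Chr2	295549	.	A	T	.	PASS	.	GT	1/1
Chr2	307637	.	C	T	.	PASS	.	GT	1/1
Chr2	307726	.	T	A	.	PASS	.	GT	1/1
Chr2	309229	.	T	A	.	PASS	.	GT	1/1
Chr2	314886	.	A	C	.	PASS	.	GT	1/1
Chr2	332219	.	G	A	.	PASS	.	GT	1/1
Chr2	333595	.	T	C	.	PASS	.	GT	1/1
Chr2	336165	.	C	G	.	PASS	.	GT	1/1
Chr2	336472	.	G	T	.	PASS	.	GT	1/1
Chr2	359233	.	C	G	.	PASS	.	GT	1/1
Chr2	393832	.	G	T	.	PASS	.	GT	1/1
Chr2	396084	.	A	T	.	PASS	.	GT	1/1
Chr2	456711	.	T	C	.	PASS	.	GT	1/1
Chr2	460431	.	C	A	.	PASS	.	GT	1/1
Chr2	462184	.	G	T	.	PASS	.	GT	1/1
Chr2	469725	.	T	C	.	PASS	.	GT	1/1
Chr2	476790	.	G	A	.	PASS	.	GT	1/1
Chr2	485341	.	A	C	.	PASS	.	GT	1/1
Chr2	490290	.	G	A	.	PASS	.	GT	1/1
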