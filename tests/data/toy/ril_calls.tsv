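chrom	pos	RIL001	RIL002	RIL003	RIL004	RIL005	RIL006	RIL007	RIL008
Chr1	2815	.	A	A	.	T	T	T	A
Chr1	16877	A	T	T	T	A	A	A	T
Chr1	35117	G	T	T	T	.	G	G	.
Chr1	41966	.	A	A	A	C	C	C	A
Chr1	48363	T	C	C	C	T	T	T	C
Chr1	49454	G	T	T	T	G	G	G	T
Chr1	69587	G	T	T	T	G	G	G	T
Chr1	71702	G	C	C	C	G	G	G	C
Chr1	100987	T	C	C	C	T	T	T	C
Chr1	106579	T	C	C	C	T	T	T	C
Chr1	108439	.	G	G	G	C	C	C	G
Chr1	109917	T	G	G	G	T	T	T	G
Chr1	137316	T	G	G	G	T	T	T	G
Chr1	141852	G	T	T	T	G	G	G	T
Chr1	148195	T	G	G	.	T	T	T	G
Chr1	148216	T	G	G	G	T	T	T	G
Chr1	153178	G	A	.	A	G	G	G	A
Chr1	164685	C	A	A	A	C	C	C	A
Chr1	198978	T	T	T	T	T	A	A	A
Chr1	242546	A	A	A	.	A	G	G	A
Chr1	249529	T	T	A	T	T	.	A	T
Chr1	266779	C	C	T	C	C	T	T	C
Chr1	274508	G	G	C	G	G	C	C	G
Chr1	286334	.	C	C	A	A	C	C	A
Chr1	300548	.	A	T	A	A	T	T	A
Chr1	347868	A	A	G	A	A	G	G	A
Chr1	349671	C	A	A	C	C	A	A	C
Chr1	365156	C	A	A	C	C	A	.	C
Chr1	379794	G	C	C	G	C	.	C	G
Chr1	392096	T	T	A	T	A	A	A	T
Chr1	393366	G	G	C	G	C	C	C	G
Chr1	393500	T	T	C	T	C	C	C	T
Chr1	398944	C	C	A	C	A	A	A	C
Chr1	417427	G	G	T	G	T	T	T	G
Chr1	423658	A	A	C	A	.	C	C	A
Chr1	428411	G	G	A	G	A	A	.	G
Chr1	461041	G	G	C	.	C	C	C	C
Chr1	463843	G	G	T	T	T	T	T	T
Chr1	465708	A	A	.	T	T	T	.	T
Chr1	468293	A	A	G	G	G	G	G	G
Chr1	476554	T	T	A	A	A	A	A	A
Chr1	484239	A	A	.	C	C	C	C	C
Chr1	487232	C	C	T	T	T	.	T	T
Chr1	498904	T	T	A	A	A	A	A	A
Chr1	515420	.	A	G	G	G	G	G	G
Chr1	533264	G	G	A	A	G	A	A	A
Chr1	577540	G	G	C	C	G	C	C	C
Chr1	590078	C	C	.	G	G	G	G	G
Chr1	596135	G	G	C	C	C	.	C	C
Chr1	596497	A	A	.	G	G	G	G	G
Chr1	597997	A	A	C	C	.	C	C	C
Chr2	8399	G	G	G	G	G	G	T	G
Chr2	9551	G	G	G	G	G	G	C	G
Chr2	13571	C	C	C	C	C	C	T	C
Chr2	29811	C	C	.	C	C	C	G	C
Chr2	36248	C	C	C	C	C	C	G	C
Chr2	58207	G	G	G	G	C	G	C	G
Chr2	59817	G	G	G	G	A	G	A	G
Chr2	70989	.	G	G	G	T	G	T	G
Chr2	79836	G	G	G	G	T	G	T	G
Chr2	80614	T	.	T	T	G	T	T	T
Chr2	99809	G	G	G	G	C	G	G	G
Chr2	112525	A	A	A	A	G	A	A	A
Chr2	124869	T	T	T	T	G	T	T	T
Chr2	137033	C	C	C	C	.	C	C	C
Chr2	146733	T	T	T	T	A	T	T	T
Chr2	156847	G	G	G	G	C	G	.	G
Chr2	163164	G	G	G	G	C	G	G	G
Chr2	173743	A	A	A	A	G	A	A	A
Chr2	192912	A	A	A	A	C	A	A	A
Chr2	196374	G	G	G	G	.	G	G	G
Chr2	215411	A	A	A	A	C	A	A	A
Chr2	221006	C	C	C	C	T	C	C	C
Chr2	227675	T	T	T	G	G	G	T	T
Chr2	231524	T	T	T	T	G	G	T	T
Chr2	240677	A	A	A	A	G	G	A	A
Chr2	263273	A	A	A	A	T	T	A	A
Chr2	268299	G	G	G	G	T	T	G	G
Chr2	307637	T	T	T	T	C	C	T	T
Chr2	307726	A	A	A	A	T	T	A	A
Chr2	309229	A	A	A	A	T	.	A	A
Chr2	314886	C	C	C	C	A	A	C	C
Chr2	321251	C	C	C	C	G	G	C	C
Chr2	332219	A	A	A	A	G	G	A	A
Chr2	333595	C	C	C	C	T	T	C	C
Chr2	336165	G	G	G	G	C	C	G	G
Chr2	336472	G	T	T	T	G	G	T	T
Chr2	349375	G	A	G	G	A	A	G	G
Chr2	359233	G	C	.	G	C	C	G	G
Chr2	373142	.	A	C	C	A	A	C	C
Chr2	392264	C	G	C	C	G	G	C	C
Chr2	396084	T	A	T	T	A	A	T	T
Chr2	460317	C	G	C	C	G	G	C	C
Chr2	460431	A	C	A	A	C	C	A	A
Chr2	462184	.	G	T	T	G	.	T	T
Chr2	465688	G	T	G	G	T	T	G	G
Chr2	467415	T	C	T	T	C	.	T	T
Chr2	469725	C	C	C	C	T	T	C	C
Chr2	470300	G	C	G	G	C	C	G	G
Chr2	476790	A	G	A	A	G	G	A	A
Chr2	485341	C	C	C	C	A	A	C	C
Chr2	490290	A	G	A	A	G	G	A	A
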