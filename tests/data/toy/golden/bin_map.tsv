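# binmapqtl v0.1.0
# config_hash=724a33675cd00794
# seed=0
bin_id	chrom	start_bp	end_bp	n_snps	n_windows	RIL001	RIL002	RIL003	RIL004	RIL005	RIL006	RIL007	RIL008
Bin0001	Chr1	2815	148195	15	1	Y	L	L	L	Y	Y	Y	L
Bin0002	Chr1	148216	392096	15	1	L	L	Y	L	Y	Y	Y	L
Bin0003	Chr1	393366	597997	21	1	L	L	Y	Y	Y	Y	Y	Y
Bin0004	Chr2	8399	146733	15	1	L	L	L	L	Y	L	Y	L
Bin0005	Chr2	156847	309229	15	1	L	L	L	L	Y	Y	L	L
Bin0006	Chr2	314886	490290	21	1	L	Y	L	L	Y	Y	L	L
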