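# binmapqtl v0.1.0
# config_hash=724a33675cd00794
# seed=0
line	chrom	left_bin	right_bin	interval_start_bp	interval_end_bp	from_genotype	to_genotype
RIL001	Chr1	Bin0001	Bin0002	148195	148216	Yugu1	Longgu7
RIL003	Chr1	Bin0001	Bin0002	148195	148216	Longgu7	Yugu1
RIL004	Chr1	Bin0002	Bin0003	392096	393366	Longgu7	Yugu1
RIL008	Chr1	Bin0002	Bin0003	392096	393366	Longgu7	Yugu1
RIL002	Chr2	Bin0005	Bin0006	309229	314886	Longgu7	Yugu1
RIL006	Chr2	Bin0004	Bin0005	146733	156847	Longgu7	Yugu1
RIL007	Chr2	Bin0004	Bin0005	146733	156847	Yugu1	Longgu7
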