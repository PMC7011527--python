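# binmapqtl v0.1.0
# config_hash=724a33675cd00794
# seed=0
bin_id	chrom	start_bp	end_bp	R	r	d_cM	cum_cM
Bin0001	Chr1	2815	148195				0.0
Bin0002	Chr1	148216	392096	0.25	0.16666666666666666	17.32867951399863	17.32867951399863
Bin0003	Chr1	393366	597997	0.25	0.16666666666666666	17.32867951399863	34.65735902799726
Bin0004	Chr2	8399	146733				0.0
Bin0005	Chr2	156847	309229	0.25	0.16666666666666666	17.32867951399863	17.32867951399863
Bin0006	Chr2	314886	490290	0.125	0.07142857142857142	7.1920518112945215	24.520731325293152
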