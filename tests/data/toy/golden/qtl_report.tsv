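# binmapqtl v0.1.0
# config_hash=724a33675cd00794
# seed=0
Trait	QTL	Environment	Chromosome	Nearest locus	Location (cM)	LOD	Additive effect	PVE (%)	Stable
SWP	qSWP1.1	E1	Chr1	Bin0002	17.33	2.73	-2.16	79.3	False
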