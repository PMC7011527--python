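"""Multi-environment QTL scan with LOD, additive effects and PVE.

Plants additive QTLs for two yield traits, scans every bin marker by
regression of trait on the parental genotype code (+1 Longgu7 / -1
Yugu1), calls peaks with LOD >= 2.0, merges QTLs across environments
with overlapping 1-LOD support intervals, and names them
q + trait + chromosome + serial.
"""

import binmapqtl as bq

genome = bq.default_genome(n_chromosomes=5, snps_per_chromosome=800)
founders = bq.simulate_founder_variants(genome, seed=4)
specific = bq.identify_specific_snps(founders.parent1, founders.parent2)
truth = bq.simulate_ril_genotypes(genome, 164, 7, seed=4)
calls = bq.simulate_observed_calls(truth, specific, 0.005, 0.05, seed=4)
bins = bq.merge_bins(bq.call_windows(bq.encode_ril_calls(calls, specific).matrix))
linkage = bq.build_linkage_map(bins)

models = [
    bq.TraitModel(
        name="SWP", grand_mean=18, phen_var=20,
        qtls=[bq.PlantedQTL("Chr2", 20_000_000, pve=0.12, sign=-1),
              bq.PlantedQTL("Chr4", 10_000_000, pve=0.08, sign=1)],
        env_effects=[0.0, 2.1, -1.5],
    ),
    bq.TraitModel(
        name="GWP", grand_mean=12, phen_var=10,
        qtls=[bq.PlantedQTL("Chr2", 22_000_000, pve=0.10, sign=-1)],
        env_effects=[0.0, 1.0, -0.5],
    ),
]
traits, planted = bq.simulate_phenotypes(truth, models, ["DH", "HN", "WW"], seed=4)

profiles = bq.genome_scan(bins, linkage, traits)
records = bq.name_qtls(bq.call_qtls(profiles))
print(bq.qtl_report(records).to_string(index=False))
print()
print("negative additive effect: the Yugu1 allele increases the trait")
print(f"stable QTLs (>=3 environments): {[r.name for r in records if r.stable]}")
clusters = bq.find_clusters(records)
if len(clusters):
    print("QTL clusters (>=2 traits within 20 cM):")
    print(clusters.to_string(index=False))
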