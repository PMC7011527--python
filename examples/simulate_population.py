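"""Simulate a biparental RIL population and inspect its ground truth.

Builds founder variant tables for two inbred parents, derives the
parent-specific SNP set, and breeds 164 F2:8 lines by single-seed
descent with Poisson crossovers.
"""

import numpy as np

import binmapqtl as bq

genome = bq.default_genome(n_chromosomes=9, snps_per_chromosome=800)
founders = bq.simulate_founder_variants(genome, seed=1)
specific = bq.identify_specific_snps(founders.parent1, founders.parent2)
truth = bq.simulate_ril_genotypes(genome, n_lines=164, n_selfing_generations=7, seed=1)

print(f"variant sites simulated:   {len(founders.reference)}")
print(f"parent-specific SNPs:      {len(specific)} "
      "(sites shared by both parents are discarded)")
n_meioses = 164 * 7 * 2 * genome.n_chromosomes
mean_xo = len(truth.crossover_log) / n_meioses
expected = np.mean(genome.chrom_genetic_lengths)
print(f"mean crossovers per gamete per chromosome: {mean_xo:.2f} "
      f"(Poisson, expected {expected:.2f} = mean genetic length in Morgans)")
het = np.mean([(g == 0.5).mean() for g in truth.genotypes.values()])
print(f"residual heterozygosity at F2:8: {het:.4f} (expected (1/2)^7 = {0.5**7:.4f})")
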