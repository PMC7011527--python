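"""From noisy RIL SNP calls to bin markers and recombination breakpoints.

Encodes calls against the parent-specific SNP set (1 = Longgu7 allele,
0 = Yugu1 allele), applies the 15-SNP sliding-window vote (sum > 10.5
calls Longgu7, < 10.5 Yugu1), merges identical consecutive windows into
bin markers and locates each line's parental transitions.
"""

import binmapqtl as bq

genome = bq.default_genome(n_chromosomes=9, snps_per_chromosome=800)
founders = bq.simulate_founder_variants(genome, seed=2)
specific = bq.identify_specific_snps(founders.parent1, founders.parent2)
truth = bq.simulate_ril_genotypes(genome, 164, 7, seed=2)
calls = bq.simulate_observed_calls(truth, specific, error_rate=0.01, missing_rate=0.10, seed=2)

encoding = bq.encode_ril_calls(calls, specific)
windows = bq.call_windows(encoding.matrix)
bins = bq.merge_bins(windows)
breakpoints, per_line = bq.detect_breakpoints(bins)
summary = bq.bin_summary(bins, breakpoints)

print(f"encoded SNPs x lines: {encoding.matrix.shape}")
print(f"windows: {len(windows.windows)}, merged into {summary['n_bins']} bin markers")
print(f"bin physical length: {summary['bin_length_bp_min'] / 1e3:.1f} kb "
      f"to {summary['bin_length_bp_max'] / 1e3:.1f} kb")
print(f"breakpoints: {summary['n_breakpoints']} total, "
      f"mean {summary['mean_breakpoints_per_line']} per line")
print("each breakpoint is a parental-origin switch between two adjacent bins")
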