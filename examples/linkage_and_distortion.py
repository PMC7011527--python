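"""Genetic map construction and segregation-distortion scan.

Adjacent-bin recombinant fractions are corrected for repeated selfing
(R = 2r/(1+2r)) and converted to centiMorgans with the Kosambi map
function; each bin is chi-square tested against 1:1 segregation, and
runs of distorted bins form segregation distortion regions (SDRs).
A transmission-bias knob plants a distorted region on Chr1.
"""

import binmapqtl as bq

genome = bq.default_genome(n_chromosomes=3, snps_per_chromosome=900)
founders = bq.simulate_founder_variants(genome, seed=3)
specific = bq.identify_specific_snps(founders.parent1, founders.parent2)
truth = bq.simulate_ril_genotypes(
    genome, 164, 7, seed=3,
    transmission_bias=("Chr1", 24_000_000, 0.7),  # Longgu7 transmitted 70:30
)
calls = bq.simulate_observed_calls(truth, specific, 0.005, 0.05, seed=3)
bins = bq.merge_bins(bq.call_windows(bq.encode_ril_calls(calls, specific).matrix))

linkage = bq.build_linkage_map(bins)
print(f"map: {linkage.summary['total_length_cM']:.2f} cM over "
      f"{linkage.summary['n_bins']} bins "
      f"({linkage.summary['mean_cM_per_bin']} cM/bin)")
for chrom, length in linkage.summary["per_chromosome_cM"].items():
    print(f"  {chrom}: {length:.1f} cM")

seg = bq.segregation_chi2(bins)
sdrs = bq.find_sdrs(seg)
print(f"distorted bins (p < 0.05): {int(seg['distorted'].sum())}/{len(seg)}")
print(f"SDRs (runs of >=5 distorted bins, common favoured parent): {len(sdrs)}")
if len(sdrs):
    peak = sdrs.iloc[0]
    print(f"  strongest SDR on {peak['chrom']} favours {peak['favored_parent']} "
          f"(peak chi2 = {peak['peak_chi2']:.1f}) — the planted 70:30 bias")
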