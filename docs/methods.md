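# Methods

This note documents the statistical models, the defaults and the
numerical choices behind `binmapqtl`, and what the simulator-based tests
do and do not demonstrate about real data.

## Population model and simulator

The simulator targets a biparental RIL design: two fully inbred
founders, an F1, then single-seed descent by selfing.  Each selfing
generation draws two gametes per individual; a gamete recombines the
two homologs with a crossover count distributed Poisson(L), L the
chromosome's genetic length in Morgans, at positions uniform on the
physical chromosome.  This is the Haldane (no-interference) model: the
study's analysis never relies on interference, and a no-interference
null is the cleanest benchmark for the map estimator.  Defaults follow
the study design the package emulates: 164 lines, 7 selfing generations
(F2:8, residual heterozygosity (1/2)^7 ≈ 0.78% per locus), 9
chromosomes of ~40 Mb whose genetic lengths average ~1.36 Morgans
(a ~12.2 Morgan genome), with SNP density reduced to desk scale
(hundreds to thousands per chromosome instead of the ~10⁴–10⁵ of real
resequencing).

Founder tables place a configurable fraction of sites (default 0.35) as
variants shared by both parents — these exercise the common-SNP
discarding step — and split the rest 0.72 : 0.28 between the parents,
mirroring the asymmetry real parent resequencing shows.  Observed calls
are derived from the true mosaic by independent per-cell missingness
(default 10%) and miscalls (default 1%), a phenomenological stand-in
for ~5× coverage genotyping; it has no read-depth or allele-balance
structure, so error is white rather than clustered.

Phenotypes are additive: value = grand mean + Σ aⱼxⱼ + environment
shift + N(0, σ²), with x = +1/−1/0 for Longgu7-homozygous /
Yugu1-homozygous / heterozygous lines.  Effects are scaled so each
planted QTL attains its target share of the phenotypic variance
(targets default to the 5.5–14.7% band typical of yield components);
σ² absorbs the remainder, and a target sum ≥ 1 is rejected.
Environment effects are additive shifts only; a G×E noise knob exists
but defaults to 0, matching the main-effects ANOVA downstream.
Segregation distortion is not modelled mechanistically; an optional
per-meiosis transmission-bias knob (probability p that the Longgu7
allele at a focal locus is transmitted) plants detectable distortion
phenomenologically.

All randomness flows from one integer seed through per-operation
`numpy` `SeedSequence` streams; SNP positions are drawn from a
dedicated stream so founder simulation and RIL simulation agree on
coordinates by construction.

## Encoding

SNPs present in both parents with the same alternate allele are
discarded; sites where the parents carry different alternates are kept,
since each allele still discriminates.  Calls matching neither parental
allele are counted and set missing rather than coded 0: conflating
genotyping error with the Yugu1 class would create false breakpoints.
A `paper_literal` flag restores the strict "1 if Longgu7, else 0" rule
for comparison.  Heterozygous calls default to missing (F2:8 lines are
nearly fixed); `drop_snp` and `major` policies are available.

## Window vote and bins

Windows are non-overlapping blocks of 15 SNPs (a step below 15 gives
overlapping, smoothed calls).  The vote threshold 10.5/15 is applied
literally and is deliberately asymmetric (≥ 11 of 15 calls Longgu7,
≤ 10 calls Yugu1); a `symmetric` option sets the cut at W/2.  With
missing SNPs the threshold scales to T·n_informative/W, keeping the
rule's operating point stable; windows with fewer than 8 informative
SNPs, or whose sum lands exactly on the scaled threshold (possible when
n_informative is a multiple of 10), are missing.  A trailing partial
window merges into the last full window.  Consecutive windows with
identical across-line genotype vectors merge into bins; a line's
missing window flanked by agreeing calls is filled (and counted as
imputed) before comparison.

A breakpoint is recorded at each genotype change along a line's bin
sequence, skipping missing bins (one count across a missing run).  The
reported physical interval is (end of left bin, start of right bin);
because the window vote localises a crossover only to within one
window, the true crossover may sit inside either flanking bin — the
recovery tests therefore assert containment within the flanking bins'
span, and exact count recovery under the condition that crossovers are
at least two windows apart and away from chromosome ends.

## Linkage map

Bins are taken in physical (reference) order; de novo grouping and
ordering are out of scope.  For adjacent bins, R = (discordant
informative lines)/(informative lines), clamped to [0, 0.5−10⁻⁶]
(clamps are logged).  The selfed-RIL correction r = R/(2(1−R)) inverts
the Haldane–Waddington fixation result R = 2r/(1+2r); distances use
Kosambi by default (the common choice of linkage packages; Haldane by
flag).  Two properties matter for interpretation:

* the correction assumes *fixed* lines.  At F2:8 the realized junction
  density is ~1.82 per Morgan versus 2.0 at fixation (measured on the
  simulator), so maps from F8 populations are genuinely ~9% shorter
  than the per-meiosis truth.  Recovery tests therefore validate the
  estimator on effectively fixed populations (20 selfing generations),
  where estimates land within a few percent of truth;
* window granularity loses crossover pairs falling within one window,
  a ~2–5% shortening at desk-scale SNP density.

The summary reports mean cM/bin as total length divided by bin count
(the convention behind "0.36 cM/bin" = 1222.26/3413) alongside the
mean per-interval distance.

Segregation is tested per bin by χ² against 1:1 on non-missing calls
(df = 1, no continuity correction); the distorted flag uses raw
p < 0.05, matching how distortion is conventionally reported for such
maps, and a Bonferroni column is emitted alongside for honest QC.  An
SDR is a maximal run of ≥ 5 consecutive distorted bins sharing a
favoured parent (the run length is configurable; published SDR counts
rest on unstated rules, so no attempt is made to match them).

## QTL scan

The scan is least-squares marker regression at bin markers only: at
0.3–3 cM marker spacing, between-marker interval mapping adds nothing.
Heterozygous or missing lines are excluded per position, keeping a
clean two-class contrast; positions where either class has fewer than
3 lines are skipped.  LOD = (n/2)·log₁₀(RSS₀/RSS₁) equals the Gaussian
likelihood-ratio statistic; the additive effect (mean_L − mean_Y)/2 is
positive when the Longgu7 allele raises the trait; PVE is the
regression R² in percent.  At LOD = 2.0 and n = 164 the per-position
null tail is P ≈ 0.0026 (F(1,162); the χ²₁ approximation gives
0.0024) — the null-calibration test asserts the Monte-Carlo rate inside
a band covering both.

QTL calling: local LOD maxima ≥ 2.0; support interval = the contiguous
region with LOD ≥ peak − 1 (a 2-LOD option exists); within one
environment overlapping candidates collapse to the strongest; across
environments candidates of the same trait and chromosome with
partially or fully overlapping intervals merge into one QTL reported
per environment.  Merging uses connected components of interval
overlap after deterministic sorting, so environment input order cannot
change the result.  Names are q + TRAIT + chromosome number + "." +
serial, serial by map position within trait × chromosome.  Stability
means detection in ≥ 3 environments; clusters are found by a greedy
left-to-right scan for ≥ 2 distinct traits peaking within 20 cM.

The optional cofactor mode approximates multiple-QTL mapping: forward
selection of marker cofactors (marginal LOD ≥ threshold, mutually
> 10 cM apart, at most 5), then a rescan conditioning on cofactors
except those within 10 cM of the tested position.  It is an
approximation by construction — no numerical equivalence with any
proprietary implementation is asserted — and the plain scan is the
default.

## Phenotype statistics

Descriptives use n−1 denominators, bias-adjusted Fisher–Pearson
skewness and bias-adjusted excess kurtosis (the defaults of common GLM
software; recorded here because shape statistics are
estimator-sensitive).  Correlations are Pearson with two-sided t
p-values, flagged at 0.05/0.01.  The ANOVA is a fixed-effects
main-effects model value ~ environment + genotype fitted by OLS with
Type-II sums of squares (identical to Type III in the absence of an
interaction term), F = MS_factor/MS_error.  The helper
`f_from_anova_sums` re-derives F from printed SS/DF; published tables
round SS to 2 decimals, so recomputed F values can differ from printed
ones in the last digit when MS_error is tiny (relative error < 0.1%).

## Problem sizes in tests and the acceptance script

Simulation-backed checks use desk-scale genomes chosen so each check
isolates one property: breakpoint recovery uses sparse crossovers
(0.3 Morgan chromosomes) so the two-window separation condition holds
for most lines; map recovery uses a dense single chromosome at 20
selfing generations; QTL recovery uses 200 replicates of a 3-chromosome
genome with one planted QTL (PVE 0.12, n = 164); null calibration
pools ~10⁵ position tests.  Passing these shows the estimators recover
the quantities the generator encodes under its assumptions (no
interference, white genotyping noise, additive QTLs); it does not by
itself certify behaviour under clustered sequencing error, segmental
coverage dropouts, or epistasis, none of which the generator emulates.

## Known limitations

* No hidden-Markov genotype refinement; the window vote is the unit of
  resolution, and breakpoints are localised to within a window.
* No de novo marker ordering or linkage grouping: reference order is
  trusted.
* No genotype-likelihood input; calls are hard alleles.
* No epistasis or QTL×environment interaction in scan or simulator;
  permutation-based genome-wide thresholds are not implemented (the
  fixed LOD ≥ 2.0 convention is).
* Real-data headline counts from the emulated study (bin totals, SDR
  and QTL counts) require the original raw sequencing data and are out
  of scope; the package reproduces the methods, not those numbers.
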