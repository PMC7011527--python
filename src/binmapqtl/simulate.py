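"""Synthetic biparental RIL populations with ground truth.

Emulates the structure of a resequenced F2:8 recombinant inbred line
(RIL) study: two inbred founders ("Longgu7" and "Yugu1") differing at
dense SNPs across nine chromosomes, single-seed-descent selfing with
Poisson (no-interference) crossovers, per-SNP genotyping error and
missingness mimicking low-coverage sequencing, and multi-environment
phenotypes with planted additive QTLs plus environment main effects.

Every stage of the analysis pipeline can therefore be tested against
recorded ground truth (parental-origin mosaics, crossover positions,
planted QTL effects) without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARENT1 = "Longgu7"
PARENT2 = "Yugu1"
_BASES = np.array(list("ACGT"))


@dataclass
class GenomeSpec:
    """Chromosome sizes and SNP density of the simulated genome.

    ``chrom_genetic_lengths`` are in Morgans (expected crossovers per
    transmitted gamete per meiosis); physical lengths in base pairs.
    """

    n_chromosomes: int
    chrom_physical_lengths: list[int]
    chrom_genetic_lengths: list[float]
    snps_per_chromosome: list[int]

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        for name in ("chrom_physical_lengths", "chrom_genetic_lengths", "snps_per_chromosome"):
            vals = getattr(self, name)
            if len(vals) != self.n_chromosomes:
                raise ValueError(f"{name} must have one entry per chromosome")
        if any(l <= 0 for l in self.chrom_physical_lengths):
            raise ValueError("physical lengths must be positive")
        if any(l < 0 for l in self.chrom_genetic_lengths):
            raise ValueError("genetic lengths must be non-negative")
        if any(n <= 0 for n in self.snps_per_chromosome):
            raise ValueError("SNP counts must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chromosomes)]


def default_genome(n_chromosomes: int = 9, snps_per_chromosome: int = 1500) -> GenomeSpec:
    """Desk-scale genome mirroring the foxtail millet map's shape.

    Nine chromosomes, ~40 Mb each, genetic lengths summing to roughly
    12 Morgans (the study map spans ~1222 cM); SNP density is reduced
    from the ~1M parent-specific SNPs of real resequencing to keep
    simulations fast while leaving ~100+ windows per chromosome.
    """
    rel = np.linspace(1.2, 0.8, n_chromosomes)
    genetic = list(12.2 / 9 * rel)  # ~1.36 Morgans per chromosome on average
    physical = [int(40e6 * f) for f in rel]
    return GenomeSpec(
        n_chromosomes=n_chromosomes,
        chrom_physical_lengths=physical,
        chrom_genetic_lengths=genetic,
        snps_per_chromosome=[snps_per_chromosome] * n_chromosomes,
    )


@dataclass
class FounderVariants:
    """Parental variant tables on a shared reference coordinate system."""

    parent1: pd.DataFrame  # chrom, pos, ref, alt — variants carried by Longgu7
    parent2: pd.DataFrame  # chrom, pos, ref, alt — variants carried by Yugu1
    reference: pd.DataFrame  # chrom, pos, ref for every simulated site


@dataclass
class TrueGenotypes:
    """Ground-truth parental origin of every line at every SNP.

    ``haplotypes[chrom]`` is an (n_lines, n_snps, 2) int8 array of
    parental origins (1 = Longgu7, 0 = Yugu1); ``genotypes[chrom]`` is
    the per-locus mean, i.e. 1.0 / 0.5 / 0.0 for Longgu7-homozygous,
    heterozygous and Yugu1-homozygous.
    """

    lines: list[str]
    positions: dict[str, np.ndarray]
    haplotypes: dict[str, np.ndarray]
    crossover_log: pd.DataFrame  # line, chrom, generation, gamete, pos_bp

    @property
    def genotypes(self) -> dict[str, np.ndarray]:
        return {c: h.mean(axis=2, dtype=np.float32) for c, h in self.haplotypes.items()}

    def genotype_frame(self) -> pd.DataFrame:
        """Lines x SNPs genotype table with a (chrom, pos) row index."""
        blocks = []
        for chrom in self.positions:
            idx = pd.MultiIndex.from_arrays(
                [np.repeat(chrom, len(self.positions[chrom])), self.positions[chrom]],
                names=["chrom", "pos"],
            )
            blocks.append(pd.DataFrame(self.genotypes[chrom].T, index=idx, columns=self.lines))
        return pd.concat(blocks)


@dataclass
class PlantedQTL:
    chrom: str
    pos_bp: int
    pve: float
    sign: int = 1
    effect: float | None = None  # trait units; derived from pve when None

    def __post_init__(self) -> None:
        if not (0 < self.pve < 1):
            raise ValueError("target PVE must lie in (0, 1)")


@dataclass
class TraitModel:
    """Additive genetic architecture of one simulated trait.

    Phenotype = grand_mean + sum_j a_j x_j + env shift + N(0, sigma^2),
    with x = +1 for Longgu7 homozygotes, -1 for Yugu1 homozygotes, 0 for
    residual heterozygotes. Effects a_j are scaled so each QTL attains
    its target PVE (share of ``phen_var``) in expectation; sigma^2 is
    the remainder of ``phen_var``.
    """

    name: str
    qtls: list[PlantedQTL] = field(default_factory=list)
    grand_mean: float = 15.0
    phen_var: float = 16.0
    env_effects: list[float] = field(default_factory=lambda: [0.0])
    gxe_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.phen_var < 0:
            raise ValueError("phenotypic variance must be >= 0")
        total_pve = sum(q.pve for q in self.qtls)
        if total_pve >= 1:
            raise ValueError(f"planted PVEs sum to {total_pve:.3f} >= 1: noise variance unreachable")


def default_trait_models(genome: GenomeSpec) -> list[TraitModel]:
    """Default yield-component trait architectures for simulate mode.

    Four traits (straw / panicle / grain weight per plant in grams and
    1000-grain weight) with 2-3 additive QTLs each, variance shares in
    the 5.5-14.7% band typical of yield components, most
    trait-increasing alleles carried by the Yugu1-type parent, and
    environment shifts of the size seen across multi-location trials.
    """
    names = genome.chrom_names
    lens = genome.chrom_physical_lengths

    def q(ci: int, frac: float, pve: float, sign: int) -> PlantedQTL:
        ci = ci % len(names)
        return PlantedQTL(chrom=names[ci], pos_bp=int(frac * lens[ci]), pve=pve, sign=sign)

    return [
        TraitModel(
            name="SWP", grand_mean=18.0, phen_var=20.0,
            qtls=[q(6, 0.55, 0.10, -1), q(8, 0.25, 0.09, -1), q(5, 0.30, 0.07, 1)],
            env_effects=[-6.4, 2.1, 0.8, 0.6, 2.5],
        ),
        TraitModel(
            name="PWP", grand_mean=16.0, phen_var=14.0,
            qtls=[q(2, 0.70, 0.10, -1), q(5, 0.60, 0.08, 1), q(8, 0.20, 0.07, -1)],
            env_effects=[-2.3, -2.5, -0.3, -2.0, 7.4],
        ),
        TraitModel(
            name="GWP", grand_mean=12.5, phen_var=10.0,
            qtls=[q(2, 0.65, 0.08, -1), q(5, 0.60, 0.11, 1), q(8, 0.50, 0.12, -1)],
            env_effects=[-2.6, -1.7, 0.5, -3.2, 7.3],
        ),
        TraitModel(
            name="TGW", grand_mean=2.9, phen_var=0.07,
            qtls=[q(7, 0.30, 0.07, -1), q(5, 0.65, 0.065, 1)],
            env_effects=[-0.24, 0.35, -0.04, -0.54, 0.49],
        ),
    ]


def _rng(seed, *spawn_key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=list(spawn_key)))


def snp_positions(genome: GenomeSpec, seed: int) -> dict[str, np.ndarray]:
    """SNP positions per chromosome, drawn from a dedicated seed stream.

    Founder and RIL simulation both derive positions from the same
    master seed, so their coordinate systems agree by construction.
    """
    rng = _rng(seed, 0)
    out = {}
    for chrom, length, n in zip(
        genome.chrom_names, genome.chrom_physical_lengths, genome.snps_per_chromosome
    ):
        if n > length:
            raise ValueError(f"{chrom}: more SNPs requested than base pairs")
        pos = np.unique(rng.integers(1, length + 1, size=2 * n))
        while len(pos) < n:  # rare at realistic densities
            pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
        out[chrom] = np.sort(rng.permutation(pos)[:n])
    return out


def simulate_founder_variants(
    genome: GenomeSpec,
    seed: int,
    common_fraction: float = 0.35,
    parent1_share: float = 0.72,
) -> FounderVariants:
    """Draw variant tables for the two founders.

    A ``common_fraction`` of sites carries the same alternate allele in
    both parents (discarded downstream as uninformative); the rest are
    parent-specific, split ``parent1_share`` : 1-share between the
    parents, mirroring the asymmetry real resequencing shows.
    Deterministic under ``seed``.
    """
    if not 0 <= common_fraction <= 1:
        raise ValueError("common_fraction must lie in [0, 1]")
    rng = _rng(seed, 1)
    positions = snp_positions(genome, seed)
    rows1, rows2, ref_rows = [], [], []
    for chrom, n_snps in zip(genome.chrom_names, genome.snps_per_chromosome):
        pos = positions[chrom]
        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
        ref, alt = _BASES[ref_idx], _BASES[alt_idx]
        u = rng.random(n_snps)
        is_common = u < common_fraction
        is_p1 = ~is_common & (rng.random(n_snps) < parent1_share)
        is_p2 = ~is_common & ~is_p1
        ref_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref}))
        rows1.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})[is_common | is_p1])
        rows2.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})[is_common | is_p2])
    return FounderVariants(
        parent1=pd.concat(rows1, ignore_index=True),
        parent2=pd.concat(rows2, ignore_index=True),
        reference=pd.concat(ref_rows, ignore_index=True),
    )


def _meiosis(hap_a, hap_b, snp_pos, length_bp, length_morgan, rng):
    """One transmitted gamete; returns (origin array, crossover bp positions)."""
    k = rng.poisson(length_morgan)
    if k == 0:
        return (hap_a if rng.random() < 0.5 else hap_b).copy(), np.empty(0)
    cuts = np.sort(rng.uniform(0, length_bp, size=k))
    parity = np.searchsorted(cuts, snp_pos, side="right") & 1
    if rng.random() < 0.5:
        parity = 1 - parity
    return np.where(parity == 0, hap_a, hap_b), cuts


def simulate_ril_genotypes(
    genome: GenomeSpec,
    n_lines: int,
    n_selfing_generations: int,
    seed: int,
    transmission_bias: tuple[str, int, float] | None = None,
) -> TrueGenotypes:
    """Single-seed-descent RILs from an F1 of the two founders.

    Each selfing generation draws two gametes per individual; each
    gamete recombines the individual's homologs with a crossover count
    ~ Poisson(chromosome genetic length in Morgans) at uniform
    positions (no interference).  ``n_selfing_generations = 7`` yields
    F2:8 lines with expected residual heterozygosity (1/2)^7 per locus.

    ``transmission_bias = (chrom, pos_bp, p)`` biases each meiosis so
    the Longgu7 allele at the nearest SNP is transmitted with
    probability ``p`` (segregation-distortion knob, default off).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if n_selfing_generations < 1:
        raise ValueError("n_selfing_generations must be >= 1")
    rng = _rng(seed, 2)
    lines = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    positions = snp_positions(genome, seed)
    haplotypes = {}
    log_rows: list[tuple] = []

    bias_chrom, bias_idx, bias_p = None, None, 0.5
    if transmission_bias is not None:
        bias_chrom, bias_bp, bias_p = transmission_bias
        if bias_chrom not in positions:
            raise ValueError(f"bias chromosome {bias_chrom!r} not in genome")
        bias_idx = int(np.argmin(np.abs(positions[bias_chrom] - bias_bp)))

    for ci, chrom in enumerate(genome.chrom_names):
        pos = positions[chrom]
        n_snps = len(pos)
        length_bp = genome.chrom_physical_lengths[ci]
        length_m = genome.chrom_genetic_lengths[ci]
        haps = np.empty((n_lines, n_snps, 2), dtype=np.int8)
        for li in range(n_lines):
            a = np.ones(n_snps, dtype=np.int8)  # Longgu7 homolog
            b = np.zeros(n_snps, dtype=np.int8)  # Yugu1 homolog
            for gen in range(1, n_selfing_generations + 1):
                gametes = []
                for gi in range(2):
                    for _attempt in range(64):
                        g, cuts = _meiosis(a, b, pos, length_bp, length_m, rng)
                        if bias_idx is None or chrom != bias_chrom:
                            break
                        keep_p = bias_p if g[bias_idx] == 1 else 1.0 - bias_p
                        if rng.random() < keep_p / max(bias_p, 1.0 - bias_p):
                            break
                    gametes.append(g)
                    for c in cuts:
                        log_rows.append((lines[li], chrom, gen, gi, float(c)))
                a, b = gametes
            haps[li, :, 0] = a
            haps[li, :, 1] = b
        haplotypes[chrom] = haps

    log = pd.DataFrame(log_rows, columns=["line", "chrom", "generation", "gamete", "pos_bp"])
    return TrueGenotypes(lines=lines, positions=positions, haplotypes=haplotypes, crossover_log=log)


def specific_positions(founders: FounderVariants) -> pd.DataFrame:
    """Parent-specific SNP table (chrom, pos, allele per parent, source).

    Convenience wrapper used by the simulator's own call writer; the
    analysis pipeline derives the same table via
    :func:`binmapqtl.encoding.identify_specific_snps`.
    """
    from .encoding import identify_specific_snps

    return identify_specific_snps(founders.parent1, founders.parent2)


def simulate_observed_calls(
    truth: TrueGenotypes,
    specific_set: pd.DataFrame,
    error_rate: float,
    missing_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Noisy per-line base calls at the parent-specific SNPs.

    Each true call is independently dropped to missing ('.') with
    ``missing_rate``, else miscalled with ``error_rate`` (a homozygous
    call flips to the other parent's allele; a heterozygous call 'H'
    collapses to a random parent's allele).  Rows are (chrom, pos),
    columns are lines, values single-character allele strings.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = _rng(seed, 3)
    geno = truth.genotypes
    blocks = []
    for chrom, grp in specific_set.groupby("chrom", sort=False):
        if chrom not in truth.positions:
            continue
        sel = np.searchsorted(truth.positions[chrom], grp["pos"].to_numpy())
        if not np.array_equal(truth.positions[chrom][sel], grp["pos"].to_numpy()):
            raise ValueError("specific-set positions absent from simulated genome")
        g = geno[chrom][:, sel]  # lines x snps, values in {0, .5, 1}
        l_allele = grp["allele_longgu7"].to_numpy()
        y_allele = grp["allele_yugu1"].to_numpy()
        calls = np.where(g == 1.0, l_allele[None, :], np.where(g == 0.0, y_allele[None, :], "H"))
        err = rng.random(g.shape) < error_rate
        if err.any():
            flip_hom = np.where(g == 1.0, y_allele[None, :], l_allele[None, :])
            rand_parent = np.where(rng.random(g.shape) < 0.5, l_allele[None, :], y_allele[None, :])
            calls = np.where(err, np.where(g == 0.5, rand_parent, flip_hom), calls)
        miss = rng.random(g.shape) < missing_rate
        calls = np.where(miss, ".", calls)
        idx = pd.MultiIndex.from_arrays(
            [np.repeat(chrom, len(grp)), grp["pos"].to_numpy()], names=["chrom", "pos"]
        )
        blocks.append(pd.DataFrame(calls.T, index=idx, columns=truth.lines))
    return pd.concat(blocks)


def simulate_phenotypes(
    truth: TrueGenotypes,
    trait_models: list[TraitModel],
    environments: list[str],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy multi-environment TraitTable plus realized per-QTL PVE.

    Returns ``(traits, realized)`` where ``traits`` has columns
    (line, environment, trait, value) and ``realized`` one row per
    planted QTL with its empirically realized variance share.
    """
    rng = _rng(seed, 4)
    n = len(truth.lines)
    geno = truth.genotypes
    rows = []
    realized_rows = []
    for model in trait_models:
        if len(model.env_effects) != len(environments):
            raise ValueError(f"trait {model.name}: need one env effect per environment")
        xs, effects = [], []
        for q in model.qtls:
            if q.chrom not in truth.positions:
                raise ValueError(f"QTL chromosome {q.chrom!r} not simulated")
            j = int(np.argmin(np.abs(truth.positions[q.chrom] - q.pos_bp)))
            x = 2.0 * geno[q.chrom][:, j] - 1.0  # +1 L hom, -1 Y hom, 0 het
            var_x = x.var()
            if var_x == 0:
                raise ValueError(f"QTL at {q.chrom}:{q.pos_bp} is monomorphic in this population")
            a = q.effect if q.effect is not None else q.sign * np.sqrt(q.pve * model.phen_var / var_x)
            xs.append(x)
            effects.append(a)
        genetic = sum(a * x for a, x in zip(effects, xs)) if xs else np.zeros(n)
        sigma2 = model.phen_var - sum(a**2 * x.var() for a, x in zip(effects, xs))
        if sigma2 < 0:
            raise ValueError(f"trait {model.name}: QTL variance exceeds phenotypic variance")
        env_vars = []
        for env, shift in zip(environments, model.env_effects):
            gxe = rng.normal(0, model.gxe_sd, size=n) if model.gxe_sd > 0 else 0.0
            y = model.grand_mean + genetic + shift + gxe + rng.normal(0, np.sqrt(sigma2), size=n)
            env_vars.append(y.var())
            rows.append(pd.DataFrame({"line": truth.lines, "environment": env, "trait": model.name, "value": y}))
        mean_env_var = float(np.mean(env_vars)) if env_vars else np.nan
        for q, a, x in zip(model.qtls, effects, xs):
            realized_rows.append(
                {
                    "trait": model.name,
                    "chrom": q.chrom,
                    "pos_bp": q.pos_bp,
                    "effect": a,
                    "target_pve": q.pve,
                    "realized_pve": a**2 * x.var() / mean_env_var if mean_env_var else np.nan,
                }
            )
    traits = pd.concat(rows, ignore_index=True)
    realized = pd.DataFrame(
        realized_rows, columns=["trait", "chrom", "pos_bp", "effect", "target_pve", "realized_pve"]
    )
    return traits, realized
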