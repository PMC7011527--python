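import numpy as np
import pandas as pd
import pytest

import binmapqtl as bq


@pytest.fixture(scope="session")
def small_genome() -> bq.GenomeSpec:
    return bq.GenomeSpec(
        n_chromosomes=3,
        chrom_physical_lengths=[30_000_000, 25_000_000, 20_000_000],
        chrom_genetic_lengths=[1.2, 1.0, 0.8],
        snps_per_chromosome=[2000, 1600, 1300],
    )


@pytest.fixture(scope="session")
def small_study(small_genome):
    """One deterministic noise-free simulated study shared across tests."""
    founders = bq.simulate_founder_variants(small_genome, seed=11, common_fraction=0.2)
    specific = bq.identify_specific_snps(founders.parent1, founders.parent2)
    truth = bq.simulate_ril_genotypes(small_genome, n_lines=120, n_selfing_generations=7, seed=11)
    calls = bq.simulate_observed_calls(truth, specific, error_rate=0.0, missing_rate=0.0, seed=11)
    encoding = bq.encode_ril_calls(calls, specific)
    bins = bq.merge_bins(bq.call_windows(encoding.matrix))
    return {
        "genome": small_genome,
        "founders": founders,
        "specific": specific,
        "truth": truth,
        "calls": calls,
        "encoding": encoding,
        "bin_map": bins,
    }


def encoded_from_codes(codes: np.ndarray, chrom: str = "Chr1") -> pd.DataFrame:
    """Build an encoded matrix from an (n_snps, n_lines) array of 1/0/NaN."""
    codes = np.asarray(codes, dtype=float)
    idx = pd.MultiIndex.from_arrays(
        [[chrom] * len(codes), np.arange(1, len(codes) + 1) * 1000], names=["chrom", "pos"]
    )
    return pd.DataFrame(codes, index=idx, columns=[f"RIL{i + 1:03d}" for i in range(codes.shape[1])])


def binmap_from_genotypes(geno: np.ndarray, chrom_of=None, spacing: int = 100_000) -> bq.BinMap:
    """Build a BinMap directly from an (n_bins, n_lines) int8 genotype array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_bins, n_lines = geno.shape
    chroms = chrom_of if chrom_of is not None else ["Chr1"] * n_bins
    bins = pd.DataFrame(
        {
            "bin_id": [f"Bin{i + 1:04d}" for i in range(n_bins)],
            "chrom": chroms,
            "start_bp": np.arange(n_bins) * spacing + 1,
            "end_bp": np.arange(n_bins) * spacing + spacing // 2,
            "n_snps": 15,
            "n_windows": 1,
        }
    )
    gdf = pd.DataFrame(geno, index=bins["bin_id"], columns=[f"RIL{i + 1:03d}" for i in range(n_lines)])
    return bq.BinMap(bins=bins, geno=gdf)
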