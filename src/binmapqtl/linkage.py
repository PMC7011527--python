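"""Genetic map construction and segregation-distortion analysis.

Bin markers are taken in physical order (reference-genome order is the
de facto order for resequencing bin maps).  For each adjacent bin pair
the observed recombinant fraction R among informative lines is
corrected for the repeated meioses of selfed RILs via the
Haldane–Waddington relation R = 2r / (1 + 2r), and the single-meiosis
fraction r is converted to centiMorgans with the Kosambi (default) or
Haldane mapping function.

Segregation distortion is tested per bin with a chi-square test against
the 1:1 expectation of a biparental RIL; runs of consecutive distorted
bins favouring the same parent form segregation distortion regions
(SDRs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binmap import BinMap, GENO_L, GENO_MISSING, GENO_Y
from .config import PipelineConfig

_R_CLAMP_EPS = 1e-6


def rf_to_r_ril(R: float | np.ndarray) -> float | np.ndarray:
    """Invert the Haldane–Waddington map for selfed RILs: r = R / (2(1-R)).

    R is the recombinant fraction observed between inbred lines, r the
    underlying single-meiosis recombination fraction (R = 2r/(1+2r) at
    fixation).  Domain: R in [0, 0.5).
    """
    R = np.asarray(R, dtype=float)
    if np.any((R < 0) | (R >= 0.5)):
        raise ValueError("observed RIL recombinant fraction must lie in [0, 0.5)")
    r = R / (2.0 * (1.0 - R))
    return float(r) if r.ndim == 0 else r


def map_distance(r: float | np.ndarray, map_function: str = "kosambi") -> float | np.ndarray:
    """Convert a single-meiosis recombination fraction to cM.

    kosambi: d = 25 ln((1+2r)/(1-2r));  haldane: d = -50 ln(1-2r).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if map_function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    elif map_function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * r)
    else:
        raise ValueError(f"unknown map function: {map_function!r}")
    return float(d) if d.ndim == 0 else d


def estimate_adjacent_rf(bin_map: BinMap) -> pd.DataFrame:
    """Observed recombinant fraction between each adjacent bin pair.

    R = (#lines with differing genotypes) / (#lines informative at
    both bins).  R is clamped to [0, 0.5 - 1e-6] before inversion;
    clamped and zero-informative intervals are flagged.
    Returns one row per interval with columns chrom, left_bin,
    right_bin, n_informative, n_recombinant, R, clamped, flagged.
    """
    bins, geno = bin_map.bins, bin_map.geno.to_numpy()
    rows = []
    for chrom in pd.unique(bins["chrom"]):
        sel = np.asarray(bins["chrom"] == chrom)
        ids = bins.loc[sel, "bin_id"].to_numpy()
        g = geno[sel]
        for i in range(len(ids) - 1):
            a, b = g[i], g[i + 1]
            inf = (a != GENO_MISSING) & (b != GENO_MISSING)
            n_inf = int(inf.sum())
            n_rec = int(np.sum(a[inf] != b[inf]))
            if n_inf == 0:
                rows.append((chrom, ids[i], ids[i + 1], 0, 0, np.nan, False, True))
                continue
            R_obs = n_rec / n_inf
            clamped = R_obs > 0.5 - _R_CLAMP_EPS
            R = min(R_obs, 0.5 - _R_CLAMP_EPS)
            rows.append((chrom, ids[i], ids[i + 1], n_inf, n_rec, R, clamped, False))
    return pd.DataFrame(
        rows,
        columns=["chrom", "left_bin", "right_bin", "n_informative", "n_recombinant", "R", "clamped", "flagged"],
    )


@dataclass
class LinkageMap:
    """Per-bin map positions plus per-interval estimates and summaries."""

    table: pd.DataFrame  # bin_id, chrom, start_bp, end_bp, R, r, d_cM, cum_cM
    intervals: pd.DataFrame  # output of estimate_adjacent_rf + r, d_cM
    summary: dict


def build_linkage_map(bin_map: BinMap, config: PipelineConfig | None = None) -> LinkageMap:
    """Cumulative genetic positions per chromosome and map summaries.

    The first bin of each chromosome sits at 0 cM; each subsequent bin
    adds the mapped distance of its interval (missing/flagged intervals
    contribute 0 and stay flagged).  The summary reports total length,
    per-chromosome lengths, and mean cM/bin computed as
    total length / #bins (the convention behind the printed
    "0.36 cM/bin": 1222.26 cM / 3413 bins) alongside the per-interval
    mean.
    """
    config = config or PipelineConfig()
    intervals = estimate_adjacent_rf(bin_map)
    r = np.full(len(intervals), np.nan)
    ok = intervals["R"].notna().to_numpy()
    r[ok] = rf_to_r_ril(intervals.loc[ok, "R"].to_numpy())
    d = np.full(len(intervals), np.nan)
    d[ok] = map_distance(r[ok], config.map_function)
    intervals = intervals.assign(r=r, d_cM=d)

    rows = []
    per_chrom = {}
    for chrom in pd.unique(bin_map.bins["chrom"]):
        sub_bins = bin_map.bins[bin_map.bins["chrom"] == chrom].reset_index(drop=True)
        sub_int = intervals[intervals["chrom"] == chrom].reset_index(drop=True)
        steps = np.nan_to_num(sub_int["d_cM"].to_numpy(), nan=0.0)
        cum = np.concatenate([[0.0], np.cumsum(steps)])
        for i in range(len(sub_bins)):
            rows.append(
                (
                    sub_bins.loc[i, "bin_id"],
                    chrom,
                    sub_bins.loc[i, "start_bp"],
                    sub_bins.loc[i, "end_bp"],
                    sub_int.loc[i - 1, "R"] if i > 0 else np.nan,
                    sub_int.loc[i - 1, "r"] if i > 0 else np.nan,
                    sub_int.loc[i - 1, "d_cM"] if i > 0 else np.nan,
                    cum[i],
                )
            )
        per_chrom[chrom] = float(cum[-1])
    table = pd.DataFrame(
        rows, columns=["bin_id", "chrom", "start_bp", "end_bp", "R", "r", "d_cM", "cum_cM"]
    )
    total = float(sum(per_chrom.values()))
    n_bins = len(bin_map.bins)
    summary = {
        "total_length_cM": total,
        "per_chromosome_cM": per_chrom,
        "n_bins": n_bins,
        "mean_cM_per_bin": round(total / n_bins, 2) if n_bins else float("nan"),
        "mean_interval_cM": float(np.nanmean(intervals["d_cM"])) if len(intervals) else float("nan"),
        "n_clamped_intervals": int(intervals["clamped"].sum()),
        "map_function": config.map_function,
    }
    return LinkageMap(table=table, intervals=intervals, summary=summary)


def segregation_chi2(bin_map: BinMap, alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square test of each bin against 1:1 parental segregation.

    Uses non-missing calls only, df = 1, no continuity correction;
    ``distorted`` flags raw p < alpha (matching the uncorrected usage in
    RIL mapping reports) and a Bonferroni-adjusted flag is emitted
    alongside.  All-missing bins are skipped (NaN statistic, flagged).
    """
    geno = bin_map.geno.to_numpy()
    n_l = np.sum(geno == GENO_L, axis=1)
    n_y = np.sum(geno == GENO_Y, axis=1)
    n_miss = np.sum(geno == GENO_MISSING, axis=1)
    n_inf = n_l + n_y
    chi2 = np.full(len(n_l), np.nan)
    p = np.full(len(n_l), np.nan)
    valid = n_inf > 0
    chi2[valid] = (n_l[valid] - n_y[valid]) ** 2 / n_inf[valid]
    p[valid] = stats.chi2.sf(chi2[valid], df=1)
    m = int(valid.sum())
    out = bin_map.bins[["bin_id", "chrom", "start_bp", "end_bp"]].copy()
    out["n_longgu7"] = n_l
    out["n_yugu1"] = n_y
    out["n_missing"] = n_miss
    out["chi2"] = chi2
    out["p_value"] = p
    out["distorted"] = valid & (p < alpha)
    out["distorted_bonferroni"] = valid & (p < alpha / max(m, 1))
    out["favored_parent"] = np.select(
        [n_l > n_y, n_y > n_l], ["Longgu7", "Yugu1"], default="none"
    )
    out["skipped"] = ~valid
    return out


def chi2_one_to_one(n_longgu7: int, n_yugu1: int) -> tuple[float, float]:
    """Chi-square statistic and p-value for counts against 1:1."""
    n = n_longgu7 + n_yugu1
    if n == 0:
        raise ValueError("no informative calls")
    chi2 = (n_longgu7 - n_yugu1) ** 2 / n
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def find_sdrs(segregation_tests: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Segregation distortion regions: maximal runs of distorted bins.

    A run of at least ``sdr_min_run`` consecutive distorted bins with a
    common favoured parent forms one SDR; its peak is the max-chi2 bin.
    Tests must be in map order.
    """
    config = config or PipelineConfig()
    rows = []
    for chrom in pd.unique(segregation_tests["chrom"]):
        sub = segregation_tests[segregation_tests["chrom"] == chrom].reset_index(drop=True)
        run_start = None
        run_parent = None
        for i in range(len(sub) + 1):
            active = (
                i < len(sub)
                and bool(sub.loc[i, "distorted"])
                and (run_parent is None or sub.loc[i, "favored_parent"] == run_parent)
            )
            if active:
                if run_start is None:
                    run_start, run_parent = i, sub.loc[i, "favored_parent"]
                continue
            if run_start is not None:
                run = sub.iloc[run_start:i]
                if len(run) >= config.sdr_min_run:
                    peak = run.loc[run["chi2"].idxmax()]
                    rows.append(
                        (
                            chrom,
                            run.iloc[0]["bin_id"],
                            run.iloc[-1]["bin_id"],
                            len(run),
                            run_parent,
                            peak["bin_id"],
                            float(peak["chi2"]),
                        )
                    )
                run_start, run_parent = None, None
            # a distorted bin with the other parent may start a new run here
            if i < len(sub) and bool(sub.loc[i, "distorted"]):
                run_start, run_parent = i, sub.loc[i, "favored_parent"]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_bin", "end_bin", "n_distorted", "favored_parent", "peak_bin", "peak_chi2"],
    )
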