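"""Sliding-window genotype calls, bin markers and recombination breakpoints.

The population's encoded SNP matrix is scanned in windows of
``window_size`` SNPs (default 15, non-overlapping).  Within a window a
line's codes are summed: a sum above the vote threshold (default 10.5,
scaled proportionally when SNPs are missing) calls the window
Longgu7-type, below it Yugu1-type.  Consecutive windows whose
across-line genotype vectors are identical merge into one *bin marker*;
a recombination breakpoint is recorded wherever a line's genotype
changes between adjacent bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

GENO_L = np.int8(1)
GENO_Y = np.int8(0)
GENO_MISSING = np.int8(-1)


@dataclass
class WindowCalls:
    """Per-window, per-line parental calls and vote sums."""

    windows: pd.DataFrame  # chrom, win_idx, start_bp, end_bp, n_snps
    calls: np.ndarray  # (n_windows, n_lines) int8: 1 / 0 / -1
    votes: np.ndarray  # (n_windows, n_lines) float vote sums
    lines: list[str]


@dataclass
class BinMap:
    """Ordered bin markers with per-line genotypes."""

    bins: pd.DataFrame  # bin_id, chrom, start_bp, end_bp, n_snps, n_windows
    geno: pd.DataFrame  # index bin_id, columns lines, int8 1 / 0 / -1
    n_imputed: int = 0

    @property
    def lines(self) -> list[str]:
        return list(self.geno.columns)


def call_windows(encoded_matrix: pd.DataFrame, config: PipelineConfig | None = None) -> WindowCalls:
    """Apply the sliding-window vote rule to an encoded SNP matrix.

    For each line and window the 1/0 codes of non-missing SNPs are
    summed and compared with the vote threshold scaled to the
    informative count, T' = T * n_informative / window_size; a sum
    above T' calls Longgu7, below T' Yugu1.  Windows with fewer than
    ``min_window_informative`` informative SNPs — or whose sum lands
    exactly on the scaled threshold — are missing.  A trailing partial
    window is merged into the last full window.
    """
    config = config or PipelineConfig()
    W, step = config.window_size, config.step
    T = config.effective_vote_threshold
    lines = list(encoded_matrix.columns)
    chrom_level = encoded_matrix.index.get_level_values("chrom")
    pos_level = encoded_matrix.index.get_level_values("pos").to_numpy()
    data = encoded_matrix.to_numpy(dtype=float)

    meta_rows, call_rows, vote_rows = [], [], []
    for chrom in pd.unique(chrom_level):
        sel = np.asarray(chrom_level == chrom)
        pos = pos_level[sel]
        block = data[sel]
        n = len(pos)
        if n == 0:
            continue
        if n <= W:
            bounds = [(0, n)]
        else:
            starts = list(range(0, n - W + 1, step))
            bounds = [(s, s + W) for s in starts]
            if bounds[-1][1] < n:  # trailing partial window -> merged into last full one
                bounds[-1] = (bounds[-1][0], n)
        for wi, (a, b) in enumerate(bounds):
            sub = block[a:b]
            n_inf = np.sum(~np.isnan(sub), axis=0)
            votes = np.nansum(sub, axis=0)
            thr = T * n_inf / W
            call = np.full(len(lines), GENO_MISSING, dtype=np.int8)
            decided = n_inf >= config.min_window_informative
            tie = np.isclose(votes, thr, rtol=0.0, atol=1e-9)
            call[decided & ~tie & (votes > thr)] = GENO_L
            call[decided & ~tie & (votes < thr)] = GENO_Y
            meta_rows.append((chrom, wi, int(pos[a]), int(pos[b - 1]), b - a))
            call_rows.append(call)
            vote_rows.append(votes)
    windows = pd.DataFrame(meta_rows, columns=["chrom", "win_idx", "start_bp", "end_bp", "n_snps"])
    return WindowCalls(
        windows=windows,
        calls=np.array(call_rows, dtype=np.int8),
        votes=np.array(vote_rows, dtype=float),
        lines=lines,
    )


def _impute_flanked_missing(calls: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill per-line missing window runs whose flanking calls agree."""
    df = pd.DataFrame(np.where(calls == GENO_MISSING, np.nan, calls))
    fwd, bwd = df.ffill(), df.bfill()
    agree = (fwd == bwd) & df.isna()
    filled = df.where(~agree, fwd)
    out = filled.fillna(GENO_MISSING).to_numpy().astype(np.int8)
    return out, int(agree.to_numpy().sum())


def merge_bins(window_calls: WindowCalls, config: PipelineConfig | None = None) -> BinMap:
    """Merge consecutive windows with identical population genotype vectors.

    Before comparing, a line's missing call inside a window is filled
    with the flanking genotype when both flanks agree (counted as
    imputed); unresolved missings stay missing and participate in the
    vector comparison as their own state.  Bin extent runs from the
    first SNP of its first window to the last SNP of its last window.
    """
    del config  # merging has no tunables; kept for signature symmetry
    meta = window_calls.windows
    bin_rows, geno_rows = [], []
    n_imputed = 0
    for chrom in pd.unique(meta["chrom"]):
        sel = (meta["chrom"] == chrom).to_numpy()
        sub_meta = meta[sel].reset_index(drop=True)
        calls, n_imp = _impute_flanked_missing(window_calls.calls[sel])
        n_imputed += n_imp
        change = np.ones(len(sub_meta), dtype=bool)
        change[1:] = np.any(calls[1:] != calls[:-1], axis=1)
        run_id = np.cumsum(change) - 1
        for rid in range(run_id[-1] + 1):
            members = np.flatnonzero(run_id == rid)
            first, last = members[0], members[-1]
            bin_rows.append(
                (
                    chrom,
                    int(sub_meta.loc[first, "start_bp"]),
                    int(sub_meta.loc[last, "end_bp"]),
                    int(sub_meta.loc[members, "n_snps"].sum()),
                    len(members),
                )
            )
            geno_rows.append(calls[first])
    bins = pd.DataFrame(bin_rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "n_windows"])
    bins.insert(0, "bin_id", [f"Bin{i + 1:04d}" for i in range(len(bins))])
    geno = pd.DataFrame(
        np.array(geno_rows, dtype=np.int8), index=bins["bin_id"], columns=window_calls.lines
    )
    return BinMap(bins=bins, geno=geno, n_imputed=n_imputed)


def detect_breakpoints(bin_map: BinMap) -> tuple[pd.DataFrame, pd.Series]:
    """Scan each line's bin-genotype sequence for parental transitions.

    Missing bins are skipped: a change across a missing run counts once,
    anchored to the physical interval between the flanking informative
    bins.  Returns the breakpoint table and per-line counts (indexed by
    every line, zero-filled).
    """
    bins = bin_map.bins
    geno = bin_map.geno.to_numpy()
    rows = []
    for chrom in pd.unique(bins["chrom"]):
        sel = (bins["chrom"] == chrom).to_numpy()
        sub = bins[sel].reset_index(drop=True)
        g = geno[sel]
        for li, line in enumerate(bin_map.lines):
            seq = g[:, li]
            inf = np.flatnonzero(seq != GENO_MISSING)
            if len(inf) < 2:
                continue
            vals = seq[inf]
            changes = np.flatnonzero(vals[1:] != vals[:-1])
            for k in changes:
                i, j = inf[k], inf[k + 1]
                rows.append(
                    (
                        line,
                        chrom,
                        sub.loc[i, "bin_id"],
                        sub.loc[j, "bin_id"],
                        int(sub.loc[i, "end_bp"]),
                        int(sub.loc[j, "start_bp"]),
                        "Longgu7" if vals[k] == GENO_L else "Yugu1",
                        "Longgu7" if vals[k + 1] == GENO_L else "Yugu1",
                    )
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "line",
            "chrom",
            "left_bin",
            "right_bin",
            "interval_start_bp",
            "interval_end_bp",
            "from_genotype",
            "to_genotype",
        ],
    )
    counts = table.groupby("line").size() if len(table) else pd.Series(dtype=int)
    counts = counts.reindex(bin_map.lines, fill_value=0).astype(int)
    counts.index.name = "line"
    return table, counts


def mean_breakpoints_per_line(total_breakpoints: int, n_lines: int) -> float:
    """Population mean breakpoints per line, reported at 2 decimals."""
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    return round(total_breakpoints / n_lines, 2)


def bin_summary(bin_map: BinMap, breakpoints: pd.DataFrame) -> dict:
    """Per-chromosome and population bin/breakpoint statistics."""
    bins = bin_map.bins
    lengths = bins["end_bp"] - bins["start_bp"] + 1
    per_chrom = (
        bins.assign(length_bp=lengths)
        .groupby("chrom", sort=False)
        .agg(n_bins=("bin_id", "size"), min_length_bp=("length_bp", "min"),
             max_length_bp=("length_bp", "max"), mean_length_bp=("length_bp", "mean"))
        .reset_index()
    )
    n_lines = len(bin_map.lines)
    total_bp = int(len(breakpoints))
    return {
        "per_chromosome": per_chrom,
        "n_bins": int(len(bins)),
        "bin_length_bp_min": int(lengths.min()) if len(bins) else 0,
        "bin_length_bp_max": int(lengths.max()) if len(bins) else 0,
        "bin_length_bp_mean": float(lengths.mean()) if len(bins) else float("nan"),
        "n_breakpoints": total_bp,
        "n_lines": n_lines,
        "mean_breakpoints_per_line": mean_breakpoints_per_line(total_bp, n_lines),
    }
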