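"""Parent-specific SNP identification and binary parental encoding.

RIL calls at parent-specific SNPs are coded 1 when they match the
Longgu7 (parent 1) allele and 0 when they match the Yugu1 (parent 2)
allele; everything downstream (window voting, bins, breakpoints, the
map) runs on this 1/0/missing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PARENT1, PARENT2

_REQUIRED = ["chrom", "pos", "ref", "alt"]


def identify_specific_snps(parent1_variants: pd.DataFrame, parent2_variants: pd.DataFrame) -> pd.DataFrame:
    """Discard SNPs common to both parents; tag the rest by source parent.

    Variants present in both tables at the same position with the same
    alternate allele are uninformative for parental origin and removed.
    Sites where the parents carry *different* alternates are kept
    (source ``"both"``): each parent's own allele still discriminates.

    Returns a table sorted by (chrom, pos) with columns
    ``chrom, pos, allele_longgu7, allele_yugu1, source``.
    """
    for name, tab in ((PARENT1, parent1_variants), (PARENT2, parent2_variants)):
        missing = [c for c in _REQUIRED if c not in tab.columns]
        if missing:
            raise ValueError(f"{name} variant table lacks columns: {missing}")
    p1 = parent1_variants[_REQUIRED].rename(columns={"ref": "ref1", "alt": "alt1"})
    p2 = parent2_variants[_REQUIRED].rename(columns={"ref": "ref2", "alt": "alt2"})
    merged = p1.merge(p2, on=["chrom", "pos"], how="outer")
    both = merged["ref1"].notna() & merged["ref2"].notna()
    conflict = both & (merged["ref1"] != merged["ref2"])
    if conflict.any():
        bad = merged.loc[conflict, ["chrom", "pos"]].iloc[0]
        raise ValueError(
            f"conflicting reference alleles at {bad['chrom']}:{bad['pos']} — "
            "parental tables are not on the same coordinate system"
        )
    common = both & (merged["alt1"] == merged["alt2"])
    merged = merged[~common].copy()

    only1 = merged["ref2"].isna()
    only2 = merged["ref1"].isna()
    shared = ~only1 & ~only2
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"].astype(np.int64),
            "allele_longgu7": np.where(only2, merged["ref2"], merged["alt1"]),
            "allele_yugu1": np.where(only1, merged["ref1"], merged["alt2"]),
            "source": np.select([only1, only2, shared], [PARENT1, PARENT2, "both"], default=""),
        }
    )
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if out.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate positions after merging parental tables")
    return out


@dataclass
class EncodingResult:
    """Encoded matrix plus QC counters."""

    matrix: pd.DataFrame  # (chrom, pos)-indexed, one float column per line: 1 / 0 / NaN
    per_chromosome: pd.DataFrame  # chrom, n_snps, n_longgu7, n_yugu1, n_het, n_missing, n_unexpected
    n_unexpected_allele: int


def encode_ril_calls(
    observed_calls: pd.DataFrame,
    specific_set: pd.DataFrame,
    het_policy: str = "missing",
    paper_literal: bool = False,
) -> EncodingResult:
    """Encode per-line allele calls into the 1/0/missing parental code.

    A call matching the Longgu7 allele becomes 1, matching the Yugu1
    allele 0, no call ('.' or empty) missing.  Heterozygous calls 'H'
    follow ``het_policy``: 'missing' (default), 'drop_snp' (discard the
    SNP row entirely) or 'major' (assign the SNP's majority parental
    class).  Calls matching neither parental allele are counted and set
    missing — unless ``paper_literal`` is true, in which case every
    non-missing call that is not the Longgu7 allele is coded 0.

    Already-encoded numeric input (values in {1, 0, NaN}) passes
    through unchanged, so encoding is idempotent.
    """
    if het_policy not in ("missing", "drop_snp", "major"):
        raise ValueError(f"unknown het policy: {het_policy!r}")

    spec = specific_set.set_index(["chrom", "pos"])
    if not observed_calls.index.isin(spec.index).all():
        raise ValueError("call matrix contains positions absent from the specific SNP set")
    spec = spec.loc[observed_calls.index]

    values = observed_calls.to_numpy()
    if np.issubdtype(values.dtype, np.number):  # already encoded
        arr = values.astype(float)
        bad = ~(np.isnan(arr) | (arr == 0) | (arr == 1))
        if bad.any():
            raise ValueError("numeric call matrix contains values other than 0/1/missing")
        encoded = arr
        het = np.zeros_like(encoded, dtype=bool)
        unexpected = np.zeros_like(het)
        missing = np.isnan(encoded)
    else:
        calls = values.astype(str)
        l_allele = spec["allele_longgu7"].to_numpy()[:, None]
        y_allele = spec["allele_yugu1"].to_numpy()[:, None]
        missing = (calls == ".") | (calls == "") | (calls == "nan")
        is_l = calls == l_allele
        is_y = calls == y_allele
        het = (calls == "H") & ~missing
        unexpected = ~missing & ~is_l & ~is_y & ~het
        encoded = np.full(calls.shape, np.nan)
        if paper_literal:
            encoded[~missing] = 0.0
            encoded[is_l] = 1.0
        else:
            encoded[is_l] = 1.0
            encoded[is_y] = 0.0
            if het_policy == "major":
                with np.errstate(invalid="ignore"):
                    major = (np.nanmean(np.where(is_l, 1.0, np.where(is_y, 0.0, np.nan)), axis=1) >= 0.5)
                encoded[het] = np.broadcast_to(major[:, None].astype(float), encoded.shape)[het]

    matrix = pd.DataFrame(encoded, index=observed_calls.index, columns=observed_calls.columns)
    if het_policy == "drop_snp" and not paper_literal:
        keep = ~het.any(axis=1)
        matrix, het, unexpected, missing = (
            matrix[keep],
            het[keep],
            unexpected[keep],
            missing[keep],
        )

    chroms = matrix.index.get_level_values("chrom")
    per_chrom = []
    enc = matrix.to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        per_chrom.append(
            {
                "chrom": chrom,
                "n_snps": int(sel.sum()),
                "n_longgu7": int(np.nansum(enc[sel] == 1.0)),
                "n_yugu1": int(np.nansum(enc[sel] == 0.0)),
                "n_het": int(het[sel].sum()),
                "n_missing": int(missing[sel].sum()),
                "n_unexpected": int(unexpected[sel].sum()),
            }
        )
    return EncodingResult(
        matrix=matrix,
        per_chromosome=pd.DataFrame(per_chrom),
        n_unexpected_allele=int(unexpected.sum()),
    )
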