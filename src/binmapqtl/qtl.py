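"""QTL scanning on the bin map: LOD profiles, QTL calling and naming.

Each bin marker is tested by least-squares regression of the trait on
the parental genotype code x (+1 Longgu7 homozygote, -1 Yugu1
homozygote; missing/heterozygous lines excluded at that position):

    LOD = (n/2) * log10(RSS0 / RSS1)
    a   = (mean_Longgu7 - mean_Yugu1) / 2
    PVE = 100 * (1 - RSS1 / RSS0)

so a positive additive effect means the Longgu7 allele increases the
trait.  Peaks with LOD >= 2.0 (default) become QTLs with 1-LOD support
intervals; within a trait, peaks from different environments whose
support intervals overlap (partially or fully) are merged into a single
QTL reported per environment.  Names follow the
"q" + trait + chromosome + "." + serial convention (e.g. qSWP7.4).

An optional cofactor mode approximates multiple-QTL mapping: marker
cofactors are forward-selected (LOD >= threshold, mutually distant,
max 5) and the genome is rescanned with cofactors as covariates,
excluding any cofactor near the tested position.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binmap import BinMap, GENO_L, GENO_MISSING, GENO_Y
from .config import PipelineConfig
from .linkage import LinkageMap


def single_position_fit(
    genotype_column: np.ndarray,
    trait_values: np.ndarray,
    min_class_n: int = 1,
) -> tuple[float, float, float]:
    """(LOD, additive effect, PVE%) of one marker against one trait.

    ``genotype_column`` uses bin codes 1 (Longgu7), 0 (Yugu1),
    -1 (missing); lines with missing genotype or trait are dropped.
    Returns NaNs when either genotype class has fewer than
    ``min_class_n`` lines; (0, a, 0) when the trait has no variance.
    """
    g = np.asarray(genotype_column)
    y = np.asarray(trait_values, dtype=float)
    keep = (g != GENO_MISSING) & ~np.isnan(y)
    g, y = g[keep], y[keep]
    is_l, is_y = g == GENO_L, g == GENO_Y
    n_l, n_y = int(is_l.sum()), int(is_y.sum())
    if n_l < min_class_n or n_y < min_class_n:
        return (np.nan, np.nan, np.nan)
    n = n_l + n_y
    rss0 = float(np.sum((y - y.mean()) ** 2))
    mean_l, mean_y = y[is_l].mean(), y[is_y].mean()
    a = (mean_l - mean_y) / 2.0
    if rss0 == 0.0:
        warnings.warn("trait has zero variance at this position; LOD set to 0")
        return (0.0, a, 0.0)
    rss1 = float(np.sum((y[is_l] - mean_l) ** 2) + np.sum((y[is_y] - mean_y) ** 2))
    if rss1 == 0.0:
        return (np.inf, a, 100.0)
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    pve = 100.0 * (1.0 - rss1 / rss0)
    return (float(lod), float(a), float(pve))


def _scan_one(geno: np.ndarray, y: np.ndarray, min_class_n: int) -> tuple[np.ndarray, ...]:
    """Vectorised marker regression of one trait vector on all bins.

    geno: (n_bins, n_lines) int8; y: (n_lines,) float with NaN missing.
    """
    ok = ~np.isnan(y)
    ml = (geno == GENO_L) & ok
    my = (geno == GENO_Y) & ok
    y0 = np.where(ok, y, 0.0)
    n_l, n_y = ml.sum(1), my.sum(1)
    syl, syy_ = ml @ y0, my @ y0
    sql, sqy = ml @ (y0**2), my @ (y0**2)
    n = n_l + n_y
    sy, sq = syl + syy_, sql + sqy
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = sq - sy**2 / n
        rss1 = (sql - syl**2 / np.maximum(n_l, 1)) + (sqy - syy_**2 / np.maximum(n_y, 1))
        a = (syl / np.maximum(n_l, 1) - syy_ / np.maximum(n_y, 1)) / 2.0
        lod = np.where(rss1 > 0, (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1), np.inf)
        pve = np.where(rss0 > 0, 100.0 * (1.0 - rss1 / np.maximum(rss0, 1e-300)), 0.0)
    lod = np.where(rss0 <= 0, 0.0, lod)
    pve = np.clip(pve, 0.0, 100.0)
    invalid = (n_l < min_class_n) | (n_y < min_class_n)
    lod[invalid] = np.nan
    a[invalid] = np.nan
    pve[invalid] = np.nan
    return lod, a, pve, n


def _select_cofactors(profile: pd.DataFrame, config: PipelineConfig) -> list[str]:
    """Forward-select cofactor bins: highest LOD first, mutually distant."""
    cand = profile[profile["LOD"] >= config.lod_threshold].sort_values("LOD", ascending=False)
    chosen: list[tuple[str, float, str]] = []
    for _, row in cand.iterrows():
        if len(chosen) >= config.max_cofactors:
            break
        if all(
            row["chrom"] != c or abs(row["cM"] - cm) > config.cofactor_window_cM
            for _, cm, c in chosen
        ):
            chosen.append((row["bin_id"], row["cM"], row["chrom"]))
    return [b for b, _, _ in chosen]


def _scan_with_cofactors(
    geno: np.ndarray,
    y: np.ndarray,
    scan_meta: pd.DataFrame,
    cofactors: list[str],
    config: PipelineConfig,
) -> tuple[np.ndarray, ...]:
    """Marker regression with cofactor covariates (MQM-like rescan)."""
    bin_ids = scan_meta["bin_id"].to_numpy()
    cof_idx = {b: i for i, b in enumerate(bin_ids)}
    cof_rows = [cof_idx[b] for b in cofactors]
    n_bins, _ = geno.shape
    lod = np.full(n_bins, np.nan)
    a = np.full(n_bins, np.nan)
    pve = np.full(n_bins, np.nan)
    n_used = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        use_cof = [
            j
            for j in cof_rows
            if scan_meta.loc[j, "chrom"] != scan_meta.loc[i, "chrom"]
            or abs(scan_meta.loc[j, "cM"] - scan_meta.loc[i, "cM"]) > config.cofactor_window_cM
        ]
        g = geno[i]
        cols = [geno[j] for j in use_cof]
        keep = (g != GENO_MISSING) & ~np.isnan(y)
        for c in cols:
            keep &= c != GENO_MISSING
        x = np.where(g[keep] == GENO_L, 1.0, -1.0)
        n_l, n_y = int((g[keep] == GENO_L).sum()), int((g[keep] == GENO_Y).sum())
        if n_l < config.min_class_n or n_y < config.min_class_n:
            continue
        yk = y[keep]
        base = np.column_stack(
            [np.ones(keep.sum())] + [np.where(c[keep] == GENO_L, 1.0, -1.0) for c in cols]
        )
        full = np.column_stack([base, x])
        rss0 = float(np.sum((yk - base @ np.linalg.lstsq(base, yk, rcond=None)[0]) ** 2))
        beta, *_ = np.linalg.lstsq(full, yk, rcond=None)
        rss1 = float(np.sum((yk - full @ beta) ** 2))
        n_used[i] = len(yk)
        if rss0 <= 0:
            lod[i], a[i], pve[i] = 0.0, beta[-1], 0.0
        elif rss1 <= 0:
            lod[i], a[i], pve[i] = np.inf, beta[-1], 100.0
        else:
            lod[i] = (len(yk) / 2.0) * np.log10(rss0 / rss1)
            a[i] = beta[-1]
            pve[i] = 100.0 * (1.0 - rss1 / rss0)
    return lod, a, pve, n_used


def genome_scan(
    bin_map: BinMap,
    linkage_map: LinkageMap,
    trait_table: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """LOD/effect/PVE profile at every bin for each trait x environment.

    Returns a long DataFrame with columns trait, environment, chrom,
    bin_id, cM, LOD, additive, PVE, n_lines.  With
    ``config.cofactor_mode`` a plain scan selects marker cofactors which
    are then conditioned on in a second pass (cofactors within
    ``cofactor_window_cM`` of the tested position are excluded).
    """
    config = config or PipelineConfig()
    scan_meta = linkage_map.table[["bin_id", "chrom", "cum_cM"]].rename(columns={"cum_cM": "cM"})
    geno = bin_map.geno.loc[scan_meta["bin_id"]].to_numpy()
    lines = bin_map.lines
    shared = set(lines) & set(trait_table["line"])
    if not shared:
        raise ValueError("no lines shared between genotype matrix and trait table")
    if len(shared) < 30:
        warnings.warn(f"only {len(shared)} lines shared between genotypes and traits")

    profiles = []
    for (trait, env), grp in trait_table.groupby(["trait", "environment"], sort=True):
        y = grp.set_index("line")["value"].reindex(lines).to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            warnings.warn(f"trait {trait!r} in {env!r} is constant; profile forced to zero")
        lod, a, pve, n = _scan_one(geno, y, config.min_class_n)
        prof = scan_meta.assign(trait=trait, environment=env, LOD=lod, additive=a, PVE=pve, n_lines=n)
        if config.cofactor_mode:
            cof = _select_cofactors(prof, config)
            if cof:
                lod, a, pve, n = _scan_with_cofactors(geno, y, scan_meta, cof, config)
                prof = scan_meta.assign(
                    trait=trait, environment=env, LOD=lod, additive=a, PVE=pve, n_lines=n
                )
        profiles.append(prof)
    out = pd.concat(profiles, ignore_index=True)
    return out[["trait", "environment", "chrom", "bin_id", "cM", "LOD", "additive", "PVE", "n_lines"]]


@dataclass
class QTLRecord:
    """One QTL, possibly supported by several environments."""

    trait: str
    chrom: str
    environments: list[str]
    peak_bin: str
    peak_cM: float
    lod: float
    additive: float
    pve: float
    ci_lo_cM: float
    ci_hi_cM: float
    stable: bool
    name: str = ""
    env_table: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class _Candidate:
    environment: str
    bin_id: str
    cM: float
    lod: float
    additive: float
    pve: float
    lo: float
    hi: float


def _peak_candidates(prof: pd.DataFrame, config: PipelineConfig) -> list[_Candidate]:
    """Local maxima with LOD >= threshold and their 1-LOD intervals."""
    lod = np.nan_to_num(prof["LOD"].to_numpy(), nan=-np.inf)
    cm = prof["cM"].to_numpy()
    n = len(lod)
    cands = []
    for i in range(n):
        if lod[i] < config.lod_threshold:
            continue
        left = lod[i - 1] if i > 0 else -np.inf
        right = lod[i + 1] if i < n - 1 else -np.inf
        if lod[i] >= left and lod[i] > right or (i == n - 1 and lod[i] >= left):
            lo = i
            while lo > 0 and lod[lo - 1] >= lod[i] - config.support_lod_drop:
                lo -= 1
            hi = i
            while hi < n - 1 and lod[hi + 1] >= lod[i] - config.support_lod_drop:
                hi += 1
            row = prof.iloc[i]
            cands.append(
                _Candidate(
                    environment=row["environment"],
                    bin_id=row["bin_id"],
                    cM=float(row["cM"]),
                    lod=float(lod[i]),
                    additive=float(row["additive"]),
                    pve=float(row["PVE"]),
                    lo=float(cm[lo]),
                    hi=float(cm[hi]),
                )
            )
    return cands


def _merge_overlapping(cands: list[_Candidate]) -> list[list[_Candidate]]:
    """Connected components of support-interval overlap (order independent)."""
    if not cands:
        return []
    cands = sorted(cands, key=lambda c: (c.lo, c.hi, c.environment, c.bin_id))
    groups = [[cands[0]]]
    reach = cands[0].hi
    for c in cands[1:]:
        if c.lo <= reach:
            groups[-1].append(c)
            reach = max(reach, c.hi)
        else:
            groups.append([c])
            reach = c.hi
    return groups


def call_qtls(profiles: pd.DataFrame, config: PipelineConfig | None = None) -> list[QTLRecord]:
    """Call QTLs from LOD profiles and merge them across environments.

    Within each trait and chromosome: per-environment local maxima with
    LOD >= threshold receive 1-LOD support intervals; within one
    environment overlapping candidates collapse to the strongest; across
    environments candidates with partially or fully overlapping
    intervals merge into one QTL carrying each environment's LOD,
    additive effect and PVE.  A QTL seen in >= 3 environments is
    flagged stable.
    """
    config = config or PipelineConfig()
    records: list[QTLRecord] = []
    if profiles.empty:
        return records
    for (trait, chrom), sub in profiles.groupby(["trait", "chrom"], sort=True):
        cands: list[_Candidate] = []
        for env in sorted(sub["environment"].unique()):
            prof = sub[sub["environment"] == env].sort_values("cM").reset_index(drop=True)
            env_cands = _peak_candidates(prof, config)
            # collapse overlapping candidates within one environment
            for grp in _merge_overlapping(env_cands):
                best = max(grp, key=lambda c: c.lod)
                best.lo = min(c.lo for c in grp)
                best.hi = max(c.hi for c in grp)
                cands.append(best)
        for grp in _merge_overlapping(cands):
            best = max(grp, key=lambda c: c.lod)
            envs = sorted({c.environment for c in grp})
            env_table = pd.DataFrame(
                [
                    {
                        "environment": c.environment,
                        "bin_id": c.bin_id,
                        "cM": c.cM,
                        "LOD": c.lod,
                        "additive": c.additive,
                        "PVE": c.pve,
                    }
                    for c in sorted(grp, key=lambda c: c.environment)
                ]
            )
            records.append(
                QTLRecord(
                    trait=trait,
                    chrom=chrom,
                    environments=envs,
                    peak_bin=best.bin_id,
                    peak_cM=best.cM,
                    lod=best.lod,
                    additive=best.additive,
                    pve=best.pve,
                    ci_lo_cM=min(c.lo for c in grp),
                    ci_hi_cM=max(c.hi for c in grp),
                    stable=len(envs) >= config.stable_min_envs,
                )
            )
            records[-1].env_table = env_table
    return records


def _chrom_number(chrom: str) -> str:
    digits = re.sub(r"\D", "", str(chrom))
    return digits.lstrip("0") or str(chrom)


def name_qtls(records: list[QTLRecord]) -> list[QTLRecord]:
    """Assign names: 'q' + trait + chromosome number + '.' + serial.

    Serial numbers run along the map within each trait x chromosome,
    starting at 1 (e.g. the fourth SWP QTL on chromosome 7 is qSWP7.4).
    """
    order = sorted(records, key=lambda r: (r.trait, str(r.chrom), r.peak_cM))
    serial: dict[tuple, int] = {}
    for rec in order:
        key = (rec.trait, rec.chrom)
        serial[key] = serial.get(key, 0) + 1
        rec.name = f"q{rec.trait}{_chrom_number(rec.chrom)}.{serial[key]}"
    return order


def find_clusters(records: list[QTLRecord], config: PipelineConfig | None = None) -> pd.DataFrame:
    """QTL clusters: >=2 QTLs for distinct traits within a ~20 cM window.

    Greedy left-to-right scan per chromosome over QTL peak positions;
    each cluster is a maximal set of peaks within ``cluster_window_cM``
    of its leftmost member covering at least two distinct traits.
    """
    config = config or PipelineConfig()
    rows = []
    by_chrom: dict[str, list[QTLRecord]] = {}
    for rec in records:
        by_chrom.setdefault(str(rec.chrom), []).append(rec)
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda r: (r.peak_cM, r.name))
        i = 0
        while i < len(peaks):
            members = [p for p in peaks[i:] if p.peak_cM <= peaks[i].peak_cM + config.cluster_window_cM]
            traits = sorted({p.trait for p in members})
            if len(members) >= 2 and len(traits) >= 2:
                rows.append(
                    {
                        "chrom": chrom,
                        "start_cM": members[0].peak_cM,
                        "end_cM": members[-1].peak_cM,
                        "n_qtls": len(members),
                        "traits": ",".join(traits),
                        "members": ",".join(p.name or p.peak_bin for p in members),
                    }
                )
                i += len(members)
            else:
                i += 1
    return pd.DataFrame(rows, columns=["chrom", "start_cM", "end_cM", "n_qtls", "traits", "members"])


def qtl_report(records: list[QTLRecord]) -> pd.DataFrame:
    """Long-format QTL table, one row per QTL x environment."""
    rows = []
    for rec in records:
        for _, er in rec.env_table.iterrows():
            rows.append(
                {
                    "Trait": rec.trait,
                    "QTL": rec.name,
                    "Environment": er["environment"],
                    "Chromosome": rec.chrom,
                    "Nearest locus": er["bin_id"],
                    "Location (cM)": round(er["cM"], 2),
                    "LOD": round(er["LOD"], 2),
                    "Additive effect": round(er["additive"], 2),
                    "PVE (%)": round(er["PVE"], 1),
                    "Stable": rec.stable,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "Trait", "QTL", "Environment", "Chromosome", "Nearest locus",
            "Location (cM)", "LOD", "Additive effect", "PVE (%)", "Stable",
        ],
    )
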