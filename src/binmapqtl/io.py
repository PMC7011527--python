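"""File formats, configuration headers and the end-to-end pipeline.

TSV (tab-delimited, UTF-8, '#'-prefixed header lines) is the canonical
interchange format; VCF is accepted for parental variant tables (read
through pysam) and written in minimal form for convenience.
Coordinates are 1-based inclusive everywhere except BED exports
(0-based half-open).  Every written artifact carries a header recording
the package version, the configuration hash and the seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binmap import BinMap, bin_summary, call_windows, detect_breakpoints, merge_bins
from .config import RunConfig
from .encoding import encode_ril_calls, identify_specific_snps
from .linkage import build_linkage_map, find_sdrs, segregation_chi2
from .phenostats import descriptive_stats, trait_correlations, two_way_anova
from .qtl import call_qtls, find_clusters, genome_scan, name_qtls, qtl_report
from .simulate import (
    default_genome,
    default_trait_models,
    simulate_founder_variants,
    simulate_observed_calls,
    simulate_phenotypes,
    simulate_ril_genotypes,
)

log = logging.getLogger("binmapqtl")

_GENO_CHAR = {1: "L", 0: "Y", -1: "-"}
_CHAR_GENO = {v: k for k, v in _GENO_CHAR.items()}


def _header_lines(config=None, seed=None) -> list[str]:
    lines = [f"# binmapqtl v{__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config.config_hash()}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    return lines


def write_tsv(df: pd.DataFrame, path: str | Path, config=None, seed=None, index: bool = False) -> Path:
    """Write a DataFrame as TSV with a '#' metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_variants(path: str | Path, fmt: str | None = None, exclude_indels: bool = True) -> pd.DataFrame:
    """Read a parental variant table from VCF or TSV.

    Returns normalized columns (chrom, pos, ref, alt); multi-allelic
    VCF records are split into one row per alternate allele; indels are
    excluded by default (bin markers are built from SNPs).
    """
    path = Path(path)
    fmt = fmt or ("vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv")
    if fmt == "vcf":
        import pysam

        rows = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    rows.append((rec.chrom, rec.pos, rec.ref, alt))
        table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    elif fmt == "tsv":
        table = read_tsv(path)
        missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: variant TSV lacks required column(s) {missing}")
        split_rows = []
        for i, row in table.iterrows():
            for alt in str(row["alt"]).split(","):
                split_rows.append((row["chrom"], row["pos"], row["ref"], alt))
        table = pd.DataFrame(split_rows, columns=["chrom", "pos", "ref", "alt"])
    else:
        raise ValueError(f"unknown variant format: {fmt!r}")
    table["pos"] = table["pos"].astype(np.int64)
    if exclude_indels:
        snv = (table["ref"].str.len() == 1) & (table["alt"].str.len() == 1)
        table = table[snv].reset_index(drop=True)
    return table


def write_vcf(variants: pd.DataFrame, path: str | Path, sample: str) -> Path:
    """Write a minimal single-sample VCF (all records homozygous alt)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=binmapqtl_v{__version__}\n")
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for _, row in variants.iterrows():
            fh.write(f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t1/1\n")
    return path


def write_call_matrix(calls: pd.DataFrame, path: str | Path, config=None, seed=None) -> Path:
    return write_tsv(calls.reset_index(), path, config, seed)


def read_call_matrix(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"chrom": str})
    return df.set_index(["chrom", "pos"])


def write_encoded_matrix(matrix: pd.DataFrame, path: str | Path, config=None, seed=None) -> Path:
    return write_tsv(matrix.reset_index(), path, config, seed)


def read_encoded_matrix(path: str | Path) -> pd.DataFrame:
    return read_tsv(path, dtype={"chrom": str}).set_index(["chrom", "pos"])


def write_bin_map(bin_map: BinMap, path: str | Path, config=None, seed=None) -> Path:
    """Bin map TSV: bin metadata then one L/Y/- genotype column per line."""
    geno_chars = bin_map.geno.replace(_GENO_CHAR)
    table = pd.concat([bin_map.bins.set_index("bin_id"), geno_chars], axis=1).reset_index()
    return write_tsv(table, path, config, seed)


def read_bin_map(path: str | Path) -> BinMap:
    df = read_tsv(path, dtype={"chrom": str})
    meta_cols = ["bin_id", "chrom", "start_bp", "end_bp", "n_snps", "n_windows"]
    bins = df[meta_cols].copy()
    geno = df.drop(columns=meta_cols).set_index(df["bin_id"])
    geno = geno.apply(lambda col: col.map(_CHAR_GENO)).astype(np.int8)
    geno.index.name = "bin_id"
    return BinMap(bins=bins, geno=geno)


def write_bed(bin_map: BinMap, path: str | Path) -> Path:
    """Bin extents as BED (0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": bin_map.bins["chrom"],
            "start": bin_map.bins["start_bp"] - 1,
            "end": bin_map.bins["end_bp"],
            "name": bin_map.bins["bin_id"],
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)
    return path


def write_traits(traits: pd.DataFrame, path: str | Path, config=None, seed=None) -> Path:
    return write_tsv(traits, path, config, seed)


def read_traits(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, dtype={"line": str, "environment": str, "trait": str})
    missing = [c for c in ("line", "environment", "trait", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trait TSV lacks required column(s) {missing}")
    return df


def run_pipeline(run_config: RunConfig) -> dict:
    """Execute encode -> binmap -> map -> segregation -> scan -> report.

    In simulate mode the inputs are drawn from the built-in RIL
    simulator under ``run_config.seed``; in real mode they are read from
    the configured paths.  Every artifact is written under
    ``run_config.out_dir`` with a version/config-hash/seed header.
    Returns the in-memory bundle of all stage results.
    """
    cfg = run_config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed

    if cfg.mode == "simulate":
        genome = default_genome(
            n_chromosomes=int(cfg.extra.get("n_chromosomes", 9)),
            snps_per_chromosome=int(cfg.extra.get("snps_per_chromosome", 1500)),
        )
        founders = simulate_founder_variants(genome, seed)
        specific = identify_specific_snps(founders.parent1, founders.parent2)
        truth = simulate_ril_genotypes(genome, cfg.n_lines, cfg.n_selfing_generations, seed)
        calls = simulate_observed_calls(truth, specific, cfg.error_rate, cfg.missing_rate, seed)
        models = default_trait_models(genome)
        traits, realized = simulate_phenotypes(
            truth, models, ["2017-DH", "2017-HN", "2017-WW", "2018-GG", "2018-HN"], seed
        )
        write_vcf(founders.parent1, out / "parent1.vcf", "Longgu7")
        write_vcf(founders.parent2, out / "parent2.vcf", "Yugu1")
        write_call_matrix(calls, out / "ril_calls.tsv", cfg, seed)
        write_traits(traits, out / "traits.tsv", cfg, seed)
        write_tsv(realized, out / "planted_qtls.tsv", cfg, seed)
        write_tsv(truth.crossover_log, out / "true_crossovers.tsv", cfg, seed)
    else:
        for field_name in ("parent1_variants", "parent2_variants", "ril_calls", "trait_file"):
            value = getattr(cfg, field_name)
            if value is None or not Path(value).exists():
                raise FileNotFoundError(f"real mode requires existing {field_name} (got {value!r})")
        p1 = read_variants(cfg.parent1_variants)
        p2 = read_variants(cfg.parent2_variants)
        specific = identify_specific_snps(p1, p2)
        calls = read_call_matrix(cfg.ril_calls)
        traits = read_traits(cfg.trait_file)

    log.info("specific SNPs: %d", len(specific))
    write_tsv(specific, out / "specific_snps.tsv", cfg, seed)

    encoding = encode_ril_calls(calls, specific, cfg.het_policy, cfg.paper_literal)
    log.info("encoded matrix: %d SNPs x %d lines (%d unexpected alleles)",
             len(encoding.matrix), encoding.matrix.shape[1], encoding.n_unexpected_allele)
    write_encoded_matrix(encoding.matrix, out / "encoded_matrix.tsv", cfg, seed)
    write_tsv(encoding.per_chromosome, out / "encoding_summary.tsv", cfg, seed)

    windows = call_windows(encoding.matrix, cfg)
    bins = merge_bins(windows, cfg)
    breakpoints, per_line = detect_breakpoints(bins)
    summary = bin_summary(bins, breakpoints)
    log.info("bins: %d; breakpoints: %d (mean %.2f/line)",
             summary["n_bins"], summary["n_breakpoints"], summary["mean_breakpoints_per_line"])
    write_bin_map(bins, out / "bin_map.tsv", cfg, seed)
    write_bed(bins, out / "bin_map.bed")
    write_tsv(breakpoints, out / "breakpoints.tsv", cfg, seed)
    write_tsv(per_line.reset_index(name="n_breakpoints"), out / "breakpoints_per_line.tsv", cfg, seed)

    linkage = build_linkage_map(bins, cfg)
    log.info("map: %.2f cM over %d bins", linkage.summary["total_length_cM"], linkage.summary["n_bins"])
    write_tsv(linkage.table, out / "linkage_map.tsv", cfg, seed)

    seg = segregation_chi2(bins)
    sdrs = find_sdrs(seg, cfg)
    log.info("distorted bins: %d; SDRs: %d", int(seg["distorted"].sum()), len(sdrs))
    write_tsv(seg, out / "segregation.tsv", cfg, seed)
    write_tsv(sdrs, out / "sdrs.tsv", cfg, seed)

    desc = descriptive_stats(traits)
    corr = trait_correlations(traits)
    anova = two_way_anova(traits)
    write_tsv(desc, out / "trait_descriptives.tsv", cfg, seed)
    write_tsv(corr, out / "trait_correlations.tsv", cfg, seed)
    write_tsv(pd.concat([t.assign(trait=k) for k, t in anova.items()]), out / "trait_anova.tsv", cfg, seed)

    profiles = genome_scan(bins, linkage, traits, cfg)
    records = name_qtls(call_qtls(profiles, cfg))
    clusters = find_clusters(records, cfg)
    report = qtl_report(records)
    log.info("QTLs: %d (%d stable); clusters: %d",
             len(records), sum(r.stable for r in records), len(clusters))
    write_tsv(profiles, out / "lod_profiles.tsv", cfg, seed)
    write_tsv(report, out / "qtl_report.tsv", cfg, seed)
    write_tsv(clusters, out / "qtl_clusters.tsv", cfg, seed)

    return {
        "specific_snps": specific,
        "encoding": encoding,
        "windows": windows,
        "bin_map": bins,
        "breakpoints": breakpoints,
        "breakpoints_per_line": per_line,
        "bin_summary": summary,
        "linkage_map": linkage,
        "segregation": seg,
        "sdrs": sdrs,
        "descriptives": desc,
        "correlations": corr,
        "anova": anova,
        "profiles": profiles,
        "qtls": records,
        "clusters": clusters,
        "qtl_report": report,
        "traits": traits,
    }
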