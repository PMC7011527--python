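"""Phenotype-level statistics for multi-environment trial tables.

Descriptive summaries per trait x environment, Pearson correlations
among traits within each environment, and a fixed-effects two-way
analysis of variance (value ~ environment + genotype) mirroring the
univariate general linear model used in yield-trait QTL studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

_TIDY_COLS = ["line", "environment", "trait", "value"]


def _check_tidy(trait_table: pd.DataFrame) -> None:
    missing = [c for c in _TIDY_COLS if c not in trait_table.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")


def descriptive_stats(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Min/max/range/mean/SD/variance/skewness/kurtosis per trait x environment.

    SD and variance use the n-1 denominator; skewness is the
    bias-adjusted Fisher–Pearson estimator and kurtosis the
    bias-adjusted excess kurtosis (the defaults of common GLM software).
    Constant samples get SD = variance = 0 with missing shape statistics.
    """
    _check_tidy(trait_table)
    rows = []
    for (trait, env), grp in trait_table.groupby(["trait", "environment"], sort=True):
        x = grp["value"].dropna().to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"need >=3 values for {trait}/{env}, got {len(x)}")
        constant = np.ptp(x) == 0
        rows.append(
            {
                "trait": trait,
                "environment": env,
                "n": len(x),
                "min": x.min(),
                "max": x.max(),
                "range": x.max() - x.min(),
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "variance": x.var(ddof=1),
                "skewness": np.nan if constant else stats.skew(x, bias=False),
                "kurtosis": np.nan if constant else stats.kurtosis(x, fisher=True, bias=False),
            }
        )
    return pd.DataFrame(rows)


def trait_correlations(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among traits within each environment.

    Returns a long table with r, the two-sided p-value and a
    significance flag ('**' p<0.01, '*' p<0.05, '' otherwise).  Pairs
    with fewer than 3 complete observations or zero variance in either
    trait are reported with missing r.
    """
    _check_tidy(trait_table)
    rows = []
    for env, grp in trait_table.groupby("environment", sort=True):
        wide = grp.pivot_table(index="line", columns="trait", values="value")
        traits = list(wide.columns)
        for i, t1 in enumerate(traits):
            for t2 in traits[i + 1 :]:
                pair = wide[[t1, t2]].dropna()
                if len(pair) < 3 or pair[t1].nunique() < 2 or pair[t2].nunique() < 2:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(pair[t1], pair[t2])
                flag = "**" if p < 0.01 else "*" if p < 0.05 else ""
                rows.append(
                    {"environment": env, "trait1": t1, "trait2": t2, "n": len(pair), "r": r, "p_value": p, "sig": flag}
                )
    return pd.DataFrame(rows)


def two_way_anova(trait_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Fixed-effects ANOVA value ~ environment + genotype, per trait.

    Main effects only (one observation per line x environment after
    plot averaging), Type-II sums of squares — equivalent to Type III
    for a main-effects model — fitted on available data.  Returns, per
    trait, a table with SS, DF, MS, F against the residual mean square,
    the p-value and a significance flag.
    """
    _check_tidy(trait_table)
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    out: dict[str, pd.DataFrame] = {}
    for trait, grp in trait_table.groupby("trait", sort=True):
        df = grp.dropna(subset=["value"])
        n_env = df["environment"].nunique()
        if n_env < 2:
            warnings.warn(f"trait {trait!r}: single environment, environment term dropped")
            model = smf.ols("value ~ C(line)", data=df).fit()
        else:
            model = smf.ols("value ~ C(environment) + C(line)", data=df).fit()
        av = sm.stats.anova_lm(model, typ=2)
        av.index = [
            i.replace("C(environment)", "Environment").replace("C(line)", "Genotype").replace("Residual", "Error")
            for i in av.index
        ]
        ms_err = av.loc["Error", "sum_sq"] / av.loc["Error", "df"]
        table = pd.DataFrame(
            {
                "factor": av.index,
                "sum_sq": av["sum_sq"].to_numpy(),
                "df": av["df"].astype(int).to_numpy(),
            }
        )
        table["mean_sq"] = table["sum_sq"] / table["df"]
        table["F"] = np.where(table["factor"] == "Error", np.nan, table["mean_sq"] / ms_err)
        table["p_value"] = [
            np.nan if f == "Error" else stats.f.sf(fv, d, av.loc["Error", "df"])
            for f, fv, d in zip(table["factor"], table["F"], table["df"])
        ]
        table["sig"] = ["" if np.isnan(p) else "**" if p < 0.01 else "*" if p < 0.05 else "" for p in table["p_value"]]
        out[trait] = table
    return out


def f_from_anova_sums(ss_factor: float, df_factor: int, ss_error: float, df_error: int) -> float:
    """F statistic recomputed from printed sums of squares and DF.

    F = (SS_factor / DF_factor) / (SS_error / DF_error), reported at the
    2-decimal precision of published ANOVA tables.
    """
    if min(df_factor, df_error) <= 0 or ss_error <= 0:
        raise ValueError("degrees of freedom and error SS must be positive")
    return round((ss_factor / df_factor) / (ss_error / df_error), 2)
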