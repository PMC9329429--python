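"""Enhancer-promoter burst-fraction coupling and distance comparisons.

The coupling analysis regresses log2 gene burst fraction on log2 enhancer
burst fraction and asks, via an interaction F-test (two-way ANOVA,
``y ~ x * group``), whether the relationship differs between conditions —
e.g. wild-type vs a cohesin-deficient genotype, where enhancer bursting
persists but no longer propagates to the promoter.  Distance distributions
between conditions are compared with the two-sided two-sample
Kolmogorov-Smirnov test on their empirical CDFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from burstlink.moments import correlate_measures

__all__ = ["CouplingFit", "KSResult", "fit_interaction", "ks_two_sample", "domain_coupling"]


@dataclass
class CouplingFit:
    slopes: dict
    intercepts: dict
    f_statistic: float
    p_value: float
    n_per_group: dict
    n_excluded: int = 0
    model: object = field(default=None, repr=False)


def fit_interaction(
    points: pd.DataFrame,
    x: str = "x",
    y: str = "y",
    group: str = "group",
    log2: bool = False,
    replicate: str | None = None,
) -> CouplingFit:
    """OLS fit of ``y ~ x * group`` with an interaction F-test.

    Per-group slopes and intercepts come from the full interaction model
    (identical to fitting each group separately); the reported p-value is
    the F-test of the full model against ``y ~ x + group``, i.e. whether
    the x-y relationship differs between groups.  With ``log2=True`` both
    variables are log2-transformed and non-positive rows are excluded
    (count reported).  ``replicate`` optionally adds an additive replicate
    covariate to both models.
    """
    cols = [x, y, group] + ([replicate] if replicate else [])
    df = points[cols].copy()
    df.columns = ["x", "y", "group"] + (["replicate"] if replicate else [])
    n_excluded = 0
    if log2:
        ok = (df["x"] > 0) & (df["y"] > 0)
        n_excluded = int((~ok).sum())
        df = df[ok]
        df["x"] = np.log2(df["x"])
        df["y"] = np.log2(df["y"])
    df = df.dropna(subset=["x", "y", "group"])
    counts = df.groupby("group").size()
    if len(counts) < 1 or (counts < 3).any():
        raise ValueError("need at least 3 points per group")

    extra = " + C(replicate)" if replicate else ""
    full = smf.ols(f"y ~ x * C(group){extra}", data=df).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("singular design: check for constant x within a group")
    reduced = smf.ols(f"y ~ x + C(group){extra}", data=df).fit()
    if len(counts) > 1:
        cmp = sm.stats.anova_lm(reduced, full)
        f_stat = float(cmp["F"].iloc[-1])
        p = float(cmp["Pr(>F)"].iloc[-1])
    else:
        f_stat, p = float("nan"), float("nan")

    groups = sorted(df["group"].unique())
    base = groups[0]
    slopes, intercepts = {}, {}
    par = full.params
    for g in groups:
        slope = par["x"]
        intercept = par["Intercept"]
        if g != base:
            slope = slope + par.get(f"x:C(group)[T.{g}]", 0.0)
            intercept = intercept + par.get(f"C(group)[T.{g}]", 0.0)
        slopes[g] = float(slope)
        intercepts[g] = float(intercept)
    return CouplingFit(
        slopes=slopes,
        intercepts=intercepts,
        f_statistic=f_stat,
        p_value=p,
        n_per_group={g: int(c) for g, c in counts.items()},
        n_excluded=n_excluded,
        model=full,
    )


@dataclass
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(d1, d2, exact: bool = False) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov comparison of distances.

    Asymptotic p-values by default (samples here are typically large);
    ``exact=True`` switches to the exact null distribution for small n.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="exact" if exact else "asymp")
    return KSResult(float(res.statistic), float(res.pvalue), a.size, b.size)


def domain_coupling(
    enh_changes: pd.DataFrame,
    gene_changes: pd.DataFrame,
    value: str = "log2_fold_change",
) -> dict:
    """Enhancer-vs-gene transcriptional change within chromatin domains.

    Both inputs need columns ``region``, ``domain``, ``condition`` and the
    ``value`` column (a per-region fold-change).  Enhancer changes are
    averaged within each (condition, domain); domains lacking a gene value
    in a condition are dropped (count reported).  Returns per-condition
    Pearson (r, p) on the domain-level pairs plus the interaction p-value
    for a condition difference in the gene-on-enhancer relationship.
    """
    e = (
        enh_changes.groupby(["condition", "domain"], sort=True)[value]
        .mean()
        .rename("enh")
        .reset_index()
    )
    g = (
        gene_changes.groupby(["condition", "domain"], sort=True)[value]
        .mean()
        .rename("gene")
        .reset_index()
    )
    merged = e.merge(g, on=["condition", "domain"], how="left")
    n_dropped = int(merged["gene"].isna().sum())
    merged = merged.dropna(subset=["gene"])

    per_condition = {}
    for cond, grp in merged.groupby("condition", sort=True):
        if len(grp) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 domains")
        per_condition[cond] = correlate_measures(grp["enh"], grp["gene"])

    interaction_p = float("nan")
    if merged["condition"].nunique() > 1:
        fit = fit_interaction(
            merged.rename(columns={"enh": "x", "gene": "y", "condition": "group"})
        )
        interaction_p = fit.p_value
    return {
        "per_condition": per_condition,
        "interaction_p": interaction_p,
        "n_domains": {c: int(n) for c, n in merged.groupby("condition").size().items()},
        "n_dropped": n_dropped,
    }
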