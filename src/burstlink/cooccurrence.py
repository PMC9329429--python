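"""Observed-vs-expected burst co-occurrence with stratified CMH testing.

If enhancer and gene burst independently, the probability of seeing both in
the same unit (cell or allele) is the product of the marginal burst
probabilities.  The analysis compares the observed co-occurrence frequency
against this product, per biological replicate, and pools replicates with a
Cochran-Mantel-Haenszel (CMH) chi-square: each replicate contributes a 2x2
table comparing the observed population against a same-size pseudo-population
whose co-occurrence count is the rounded expected count.  Marginals are
estimated within replicate, never pooled, so replicate-to-replicate shifts
in burst fraction cannot masquerade as coupling (Simpson's-paradox guard).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from burstlink.pairing import assign_cis_pairs

__all__ = [
    "expected_cooccurrence",
    "ContingencyStratum",
    "CooccurrenceResult",
    "build_strata",
    "cmh_test",
    "bonferroni",
    "cooccurrence_analysis",
    "binomial_check",
]


def expected_cooccurrence(p_a: float, p_b: float) -> float:
    """Expected co-occurrence under independence: the product of marginals."""
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return p_a * p_b


@dataclass(frozen=True)
class ContingencyStratum:
    """2x2 table for one replicate: observed vs expected pseudo-population.

    Rows are (observed population, expected population); columns are
    (co-occurring, not co-occurring).
    """

    replicate_id: object
    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be >= 0")
        if self.n11 + self.n10 + self.n01 + self.n00 == 0:
            raise ValueError("contingency table must have a positive total")


def build_strata(
    observed: dict | pd.Series,
    expected_prob: dict | pd.Series,
    totals: dict | pd.Series,
) -> list[ContingencyStratum]:
    """One 2x2 stratum per replicate.

    ``observed[r]`` is the co-occurrence count among ``totals[r]`` units in
    replicate ``r``; the comparison row is a same-size population with
    ``round(totals[r] * expected_prob[r])`` co-occurrences.
    """
    strata = []
    for rep in observed.keys() if isinstance(observed, dict) else observed.index:
        n = int(totals[rep])
        if n < 1:
            warnings.warn(f"replicate {rep!r} has no units; stratum dropped")
            continue
        obs = int(observed[rep])
        p = float(expected_prob[rep])
        if p == 0.0 and obs > 0:
            warnings.warn(
                f"replicate {rep!r}: expected probability 0 with observed {obs}; "
                "stratum kept with expected count 0"
            )
        exp = int(round(n * p))
        strata.append(ContingencyStratum(rep, obs, n - obs, exp, n - exp))
    return strata


def cmh_test(
    strata: list[ContingencyStratum],
    correction: bool = False,
) -> tuple[float, float]:
    """Mantel-Haenszel chi-square over 2x2 strata.

    ``T = (sum_k (n11_k - E_k))^2 / sum_k V_k`` with the hypergeometric
    mean ``E = r1*c1/N`` and variance ``V = r1*r2*c1*c2 / (N^2*(N-1))`` per
    stratum; p from chi-square with 1 df.  No continuity correction by
    default (``correction=True`` subtracts 0.5 from the absolute deviation).
    Degenerate strata (a zero margin) contribute nothing; if all are
    degenerate the test is undefined and (nan, nan) is returned.
    """
    dev = 0.0
    var = 0.0
    for s in strata:
        r1 = s.n11 + s.n10
        r2 = s.n01 + s.n00
        c1 = s.n11 + s.n01
        c2 = s.n10 + s.n00
        n = r1 + r2
        if n < 2 or r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
            continue
        dev += s.n11 - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1.0))
    if var == 0.0:
        return float("nan"), float("nan")
    num = abs(dev) - (0.5 if correction else 0.0)
    stat = max(num, 0.0) ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m*p)`` per p-value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m_eff = len(p) if m is None else int(m)
    if m_eff < len(p):
        raise ValueError("m must be >= the number of tests")
    return np.minimum(1.0, m_eff * p)


def binomial_check(strata: list[ContingencyStratum]) -> float:
    """Pooled exact binomial cross-check of the CMH comparison.

    Tests the pooled observed co-occurrence count against the pooled
    expected probability; a secondary diagnostic, not the headline test.
    """
    n = sum(s.n11 + s.n10 for s in strata)
    k = sum(s.n11 for s in strata)
    p = sum(s.n01 for s in strata) / n if n else float("nan")
    if n == 0 or not 0 <= p <= 1:
        return float("nan")
    return float(stats.binomtest(k, n, p).pvalue)


@dataclass
class CooccurrenceResult:
    level: str
    probe_a: str
    probe_b: str
    observed_freq: float
    expected_freq: float
    ratio: float
    cmh_statistic: float
    p_value: float
    n_strata: int
    p_adjusted: float = float("nan")
    strata: list[ContingencyStratum] = field(default_factory=list, repr=False)


def _per_replicate_frames(cells: pd.DataFrame) -> pd.Series:
    return cells.groupby("replicate_id", sort=True).size()


def cooccurrence_analysis(
    tss: pd.DataFrame,
    cells: pd.DataFrame,
    probe_a: str,
    probe_b: str,
    level: str = "allele",
    ploidy: int = 2,
    threshold: float = 1.0,
    pairs: pd.DataFrame | None = None,
) -> CooccurrenceResult:
    """Observed-vs-expected co-occurrence of bursts of two probes.

    ``level="cell"``: the unit is a cell; events are ">= 1 burst of probe_a"
    and ">= 1 burst of probe_b".  With ``probe_a == probe_b`` the event pair
    becomes bi-allelic bursting (>= 2 bursts of the probe) against the
    squared allele-level burst probability.

    ``level="allele"``: the unit is an allele slot (ploidy x cells);
    observed co-occurrences are cis-matched enhancer-gene pairs (xy distance
    below ``threshold``; matching is mutual-nearest-neighbour), expected is
    the product of the allele-level marginal burst fractions.

    Marginals and expecteds are computed per replicate; replicates are
    pooled by the CMH test.  Call on one condition at a time.
    """
    if level not in ("cell", "allele"):
        raise ValueError("level must be 'cell' or 'allele'")
    meta = cells[["cell_id", "replicate_id"]]
    n_cells = _per_replicate_frames(cells)
    t = tss.merge(meta, on="cell_id", how="left")

    observed: dict = {}
    expected: dict = {}
    totals: dict = {}

    if level == "cell":
        for rep, n in n_cells.items():
            sub = t[t["replicate_id"] == rep]
            per_cell = sub.groupby(["cell_id", "probe_id"]).size().unstack(fill_value=0)
            ca = per_cell[probe_a] if probe_a in per_cell else pd.Series(dtype=int)
            if probe_a == probe_b:
                n_bursts = int(ca.sum())
                p_allele = n_bursts / (ploidy * n) if n else np.nan
                observed[rep] = int((ca >= 2).sum())
                expected[rep] = p_allele**2
            else:
                cb = per_cell[probe_b] if probe_b in per_cell else pd.Series(dtype=int)
                both = (ca >= 1) & (cb >= 1).reindex(ca.index, fill_value=False)
                observed[rep] = int(both.sum())
                expected[rep] = expected_cooccurrence(
                    float((ca >= 1).sum()) / n, float((cb >= 1).sum()) / n
                )
            totals[rep] = int(n)
    else:
        if probe_a == probe_b:
            raise ValueError("allele-level analysis needs two distinct probes")
        if pairs is None:
            enh = tss[tss["probe_id"] == probe_a]
            gene = tss[tss["probe_id"] == probe_b]
            pairs = assign_cis_pairs(enh, gene, threshold=threshold)
        p = pairs.merge(meta, on="cell_id", how="left")
        for rep, n in n_cells.items():
            slots = ploidy * int(n)
            sub = t[t["replicate_id"] == rep]
            na = int((sub["probe_id"] == probe_a).sum())
            nb = int((sub["probe_id"] == probe_b).sum())
            observed[rep] = int((p["replicate_id"] == rep).sum())
            expected[rep] = expected_cooccurrence(na / slots, nb / slots)
            totals[rep] = slots

    strata = build_strata(observed, expected, totals)
    tot_units = sum(totals.values())
    obs_freq = sum(observed.values()) / tot_units if tot_units else np.nan
    exp_count = sum(totals[r] * expected[r] for r in totals)
    exp_freq = exp_count / tot_units if tot_units else np.nan
    ratio = obs_freq / exp_freq if exp_freq > 0 else np.nan
    stat, pval = cmh_test(strata)
    return CooccurrenceResult(
        level=level,
        probe_a=probe_a,
        probe_b=probe_b,
        observed_freq=float(obs_freq),
        expected_freq=float(exp_freq),
        ratio=float(ratio),
        cmh_statistic=stat,
        p_value=pval,
        n_strata=len(strata),
        strata=strata,
    )
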