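"""Allele assignment of enhancer and promoter bursts by nuclear distance.

In a diploid nucleus two bursts of the *same* probe necessarily sit on
homologous chromosomes (trans), so the distribution of same-probe pair
distances calibrates how far apart two alleles are.  A cross-probe
(enhancer-gene) pair closer than the low quantile of that trans distribution
is assigned to the same allele (cis).  All distances are xy-only: the axial
(z) localisation is much less precise and is carried for diagnostics but
never used for assignment.  Chromatic aberration between channels is left
uncorrected, so the calibrated threshold absorbs it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from burstlink.errors import CalibrationError

__all__ = [
    "xy_distance",
    "pair_distances",
    "calibrate_threshold",
    "assign_cis_pairs",
]


def xy_distance(a, b) -> float:
    """Euclidean distance between two TSS records in the xy plane (um)."""
    if a["cell_id"] != b["cell_id"]:
        raise ValueError("xy_distance is only defined within one cell")
    return float(np.hypot(a["x"] - b["x"], a["y"] - b["y"]))


def _cross_join(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    m = left.merge(right, on="cell_id", suffixes=("_a", "_b"))
    m["xy_distance"] = np.hypot(m["x_a"] - m["x_b"], m["y_a"] - m["y_b"])
    m["distance_3d"] = np.sqrt(
        (m["x_a"] - m["x_b"]) ** 2 + (m["y_a"] - m["y_b"]) ** 2 + (m["z_a"] - m["z_b"]) ** 2
    )
    return m


def pair_distances(tss: pd.DataFrame, probe_a: str, probe_b: str) -> pd.DataFrame:
    """All within-cell TSS pairs between two probes (or bi-allelic pairs).

    For ``probe_a != probe_b`` every cross pair in each cell is returned;
    for ``probe_a == probe_b`` each unordered same-probe pair once
    (bi-allelic pairs).  Columns: cell_id, pair_type, tss_id_a, tss_id_b,
    xy_distance, distance_3d.
    """
    cols = ["tss_id", "cell_id", "x", "y", "z"]
    ta = tss.loc[tss["probe_id"] == probe_a, cols]
    tb = tss.loc[tss["probe_id"] == probe_b, cols]
    m = _cross_join(ta, tb)
    if probe_a == probe_b:
        m = m[m["tss_id_a"] < m["tss_id_b"]]
    m = m[["cell_id", "tss_id_a", "tss_id_b", "xy_distance", "distance_3d"]].copy()
    m.insert(1, "pair_type", f"{probe_a}|{probe_b}")
    return m.reset_index(drop=True)


def calibrate_threshold(
    biallelic_distances,
    q: float = 0.05,
    min_pairs: int = 20,
    default: float = 1.0,
) -> float:
    """Same-allele distance threshold from bi-allelic (trans) pair distances.

    Returns the q-th lower empirical quantile (type 1, the ``ceil(q*n)``-th
    order statistic): below this distance a cross-probe pair is same-allele
    with confidence >= 1-q, because trans pairs rarely come that close.
    With fewer than ``min_pairs`` distances the configured ``default`` is
    returned with a warning (or :class:`CalibrationError` if ``default`` is
    None).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    d = np.sort(np.asarray(biallelic_distances, dtype=float))
    if d.size < min_pairs:
        msg = (
            f"only {d.size} bi-allelic pair distances (need >= {min_pairs}); "
            f"falling back to the default threshold {default} um"
        )
        if default is None:
            raise CalibrationError(msg)
        warnings.warn(msg)
        return float(default)
    k = int(np.ceil(q * d.size)) - 1
    return float(d[max(k, 0)])


def assign_cis_pairs(
    enh_tss: pd.DataFrame,
    gene_tss: pd.DataFrame,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Match enhancer and gene bursts on the same allele.

    Within each cell, cross-probe pairs with xy distance < ``threshold``
    are matched by iterated mutual nearest neighbours (equivalently: accept
    the closest remaining pair, remove both members, repeat).  Ties are
    broken by smaller distance, then lexicographic TSS ids, making the
    matching deterministic and symmetric in the two probes.  Matched pairs
    in a cell are labelled allele ``A``, ``B``, ... in order of distance.

    Returns columns: cell_id, enh_tss_id, gene_tss_id, xy_distance,
    distance_3d, allele_label.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    cols = ["tss_id", "cell_id", "x", "y", "z"]
    cand = _cross_join(enh_tss[cols], gene_tss[cols])
    cand = cand[cand["xy_distance"] < threshold]
    out_cols = ["cell_id", "enh_tss_id", "gene_tss_id", "xy_distance", "distance_3d", "allele_label"]
    if cand.empty:
        return pd.DataFrame(columns=out_cols)
    # symmetric tie-break: distance, then the sorted id pair
    lo = np.minimum(cand["tss_id_a"], cand["tss_id_b"])
    hi = np.maximum(cand["tss_id_a"], cand["tss_id_b"])
    cand = cand.assign(_lo=lo, _hi=hi).sort_values(
        ["cell_id", "xy_distance", "_lo", "_hi"], kind="mergesort"
    )

    # fast path: cells with a single candidate pair are trivially matched
    n_cand = cand.groupby("cell_id")["tss_id_a"].transform("size")
    single = cand[n_cand == 1]
    multi = cand[n_cand > 1]

    parts = []
    if not single.empty:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": single["cell_id"].to_numpy(),
                    "enh_tss_id": single["tss_id_a"].to_numpy(),
                    "gene_tss_id": single["tss_id_b"].to_numpy(),
                    "xy_distance": single["xy_distance"].to_numpy(),
                    "distance_3d": single["distance_3d"].to_numpy(),
                    "allele_label": "A",
                }
            )
        )
    rows = []
    for cell_id, grp in multi.groupby("cell_id", sort=True):
        used_a: set = set()
        used_b: set = set()
        n_matched = 0
        for rec in grp.itertuples(index=False):
            if rec.tss_id_a in used_a or rec.tss_id_b in used_b:
                continue
            used_a.add(rec.tss_id_a)
            used_b.add(rec.tss_id_b)
            rows.append(
                (
                    cell_id,
                    rec.tss_id_a,
                    rec.tss_id_b,
                    rec.xy_distance,
                    rec.distance_3d,
                    chr(ord("A") + n_matched),
                )
            )
            n_matched += 1
    if rows:
        parts.append(pd.DataFrame(rows, columns=out_cols))
    if not parts:
        return pd.DataFrame(columns=out_cols)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["cell_id", "xy_distance"], kind="mergesort").reset_index(drop=True)
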