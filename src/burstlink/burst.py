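"""TSS burst calling and burst-parameter quantification.

During a transcriptional burst the TSS accumulates nascent transcripts and
appears as a nuclear focus brighter than a single molecule.  Burst calling is
therefore ratio-based: a nuclear spot is a TSS candidate when its integrated
intensity exceeds ``tau`` times the single-molecule reference intensity
``I1`` of its probe, and at most ``ploidy`` candidates (the brightest) are
kept per cell.  Burst intensity is the intensity/I1 ratio, a proxy for the
number of nascent transcripts; burst fraction is the fraction of alleles
(default) or cells with a called burst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from burstlink.errors import ReferenceError_
from burstlink.io import Dataset

__all__ = [
    "single_molecule_reference",
    "call_tss",
    "burst_fraction",
    "decompose_expression",
    "mature_counts",
    "burst_summary",
]

TSS_COLUMNS = ["tss_id", "cell_id", "probe_id", "x", "y", "z", "burst_intensity", "allele_label"]


def single_molecule_reference(
    spots: pd.DataFrame,
    min_spots: int = 20,
    trim_quantile: float = 0.9,
) -> float:
    """Robust single-molecule intensity I1 for one probe.

    Uses cytoplasmic spots when at least ``min_spots`` are available,
    otherwise falls back to nuclear (sub-TSS) spots.  The estimate is the
    median of intensities at or below the ``trim_quantile`` empirical
    quantile; trimming the top decile guards against undetected aggregates
    and nascent foci leaking into the reference pool.
    """
    cyto = spots.loc[spots["compartment"] == "cytoplasmic", "intensity"].to_numpy(float)
    vals = cyto
    if vals.size < min_spots:
        vals = spots.loc[spots["compartment"] == "nuclear", "intensity"].to_numpy(float)
    if vals.size < min_spots:
        raise ReferenceError_(
            f"only {vals.size} spots available for the single-molecule reference "
            f"(need >= {min_spots}); pool spots across replicates and retry"
        )
    cut = np.quantile(vals, trim_quantile)
    return float(np.median(vals[vals <= cut]))


def call_tss(
    spots: pd.DataFrame,
    i1: float,
    tau: float = 2.0,
    ploidy: int = 2,
) -> pd.DataFrame:
    """Call TSS bursts for one probe.

    Nuclear spots with intensity >= ``tau * i1`` become candidates; per cell
    the ``ploidy`` brightest are kept (a diploid cell cannot host more than
    two true TSS foci per locus — extra candidates are treated as the
    brighter of segmentation doublets, capped rather than discarded).
    Returns a TSS table with ``burst_intensity = intensity / i1``.
    """
    if i1 <= 0:
        raise ValueError("i1 must be > 0")
    if tau <= 1:
        raise ValueError("tau must be > 1 (a burst is brighter than one molecule)")
    cand = spots[(spots["compartment"] == "nuclear") & (spots["intensity"] >= tau * i1)]
    cand = cand.sort_values(
        ["intensity", "spot_id"], ascending=[False, True], kind="mergesort"
    )
    kept = cand.groupby(["cell_id", "probe_id"], sort=False).head(ploidy)
    tss = pd.DataFrame(
        {
            "tss_id": kept["spot_id"].to_numpy(),
            "cell_id": kept["cell_id"].to_numpy(),
            "probe_id": kept["probe_id"].to_numpy(),
            "x": kept["x"].to_numpy(float),
            "y": kept["y"].to_numpy(float),
            "z": kept["z"].to_numpy(float),
            "burst_intensity": kept["intensity"].to_numpy(float) / i1,
            "allele_label": "unassigned",
        }
    )
    return tss.sort_values("tss_id", kind="mergesort").reset_index(drop=True)


def burst_fraction(
    tss: pd.DataFrame,
    cells: pd.DataFrame,
    ploidy: int = 2,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Burst fraction per (condition, replicate_id, probe_id).

    Default denominator is alleles (``ploidy`` x cells): the fraction of
    actively transcribing alleles.  With ``per_cell=True`` the numerator is
    the number of cells with at least one called burst and the denominator
    the number of cells.
    """
    groups = cells.groupby(["condition", "replicate_id"], sort=True).size().rename("n_cells")
    meta = cells[["cell_id", "condition", "replicate_id"]]
    merged = tss.merge(meta, on="cell_id", how="left")
    probes = sorted(tss["probe_id"].unique())
    out_rows = []
    for probe in probes:
        sub = merged[merged["probe_id"] == probe]
        if per_cell:
            counts = (
                sub.drop_duplicates("cell_id")
                .groupby(["condition", "replicate_id"], sort=True)
                .size()
            )
        else:
            counts = sub.groupby(["condition", "replicate_id"], sort=True).size()
        for (cond, rep), n_cells in groups.items():
            n_bursts = int(counts.get((cond, rep), 0))
            denom = n_cells if per_cell else ploidy * n_cells
            if denom == 0:
                warnings.warn(f"sample ({cond}, {rep}) has zero cells; burst fraction undefined")
                frac = np.nan
            else:
                frac = n_bursts / denom
            out_rows.append(
                {
                    "condition": cond,
                    "replicate_id": rep,
                    "probe_id": probe,
                    "n_cells": int(n_cells),
                    "n_bursts": n_bursts,
                    "burst_fraction": frac,
                }
            )
    return pd.DataFrame(out_rows)


def decompose_expression(
    counts: np.ndarray | pd.Series,
    threshold: int = 5,
) -> tuple[float, float]:
    """Split expression into (fraction expressing, mean count among them).

    ``fraction`` is the share of cells with at least ``threshold``
    transcripts; ``mean`` is the mean count over exactly those cells (NaN
    when no cell passes).  Separates how many cells express from how much
    the expressing cells make.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        return 0.0, float("nan")
    if (arr < 0).any():
        raise ValueError("counts must be >= 0")
    pos = arr >= threshold
    frac = float(pos.mean())
    mean = float(arr[pos].mean()) if pos.any() else float("nan")
    return frac, mean


def mature_counts(dataset: Dataset, probe_id: str) -> pd.Series:
    """Cytoplasmic transcript count per cell for one probe (zeros included)."""
    spots = dataset.spots
    sel = spots[(spots["probe_id"] == probe_id) & (spots["compartment"] == "cytoplasmic")]
    counts = sel.groupby("cell_id").size()
    return counts.reindex(dataset.cells["cell_id"], fill_value=0).astype(int)


@dataclass
class QuantifyResult:
    """Output of :func:`burst_summary`: per-sample table plus TSS records."""

    summary: pd.DataFrame
    tss: pd.DataFrame
    i1: dict[str, float]


def burst_summary(
    dataset: Dataset,
    tau: float = 2.0,
    ploidy: int = 2,
    count_probe: str | None = None,
    expression_threshold: int = 5,
    per_cell: bool = False,
    min_reference_spots: int = 20,
) -> QuantifyResult:
    """End-to-end burst quantification for every probe in a dataset.

    For each probe: estimate I1, call TSS bursts, then summarise per
    (condition, replicate_id, probe_id): number of cells and bursts, burst
    fraction, mean/median burst intensity and — when ``count_probe`` is
    given — mean mature-mRNA count and the fraction of cells expressing at
    least ``expression_threshold`` transcripts of that probe.
    """
    spots = dataset.spots
    tss_parts = []
    i1_by_probe: dict[str, float] = {}
    for probe in sorted(spots["probe_id"].unique()):
        sub = spots[spots["probe_id"] == probe]
        i1 = single_molecule_reference(sub, min_spots=min_reference_spots)
        i1_by_probe[probe] = i1
        tss_parts.append(call_tss(sub, i1, tau=tau, ploidy=ploidy))
    tss = (
        pd.concat(tss_parts, ignore_index=True)
        if tss_parts
        else pd.DataFrame(columns=TSS_COLUMNS)
    )

    summary = burst_fraction(tss, dataset.cells, ploidy=ploidy, per_cell=per_cell)

    meta = dataset.cells[["cell_id", "condition", "replicate_id"]]
    merged = tss.merge(meta, on="cell_id", how="left")
    bi = (
        merged.groupby(["condition", "replicate_id", "probe_id"], sort=True)["burst_intensity"]
        .agg(mean_burst_intensity="mean", median_burst_intensity="median")
        .reset_index()
    )
    summary = summary.merge(bi, on=["condition", "replicate_id", "probe_id"], how="left")

    if count_probe is not None:
        counts = mature_counts(dataset, count_probe)
        tab = pd.DataFrame(
            {
                "cell_id": dataset.cells["cell_id"].to_numpy(),
                "condition": dataset.cells["condition"].to_numpy(),
                "replicate_id": dataset.cells["replicate_id"].to_numpy(),
                "count": counts.to_numpy(),
            }
        )
        rows = []
        for (cond, rep), grp in tab.groupby(["condition", "replicate_id"], sort=True):
            frac, mean_pos = decompose_expression(grp["count"], expression_threshold)
            rows.append(
                {
                    "condition": cond,
                    "replicate_id": rep,
                    "mean_mrna_count": float(grp["count"].mean()),
                    "fraction_expressing": frac,
                    "mean_count_expressing": mean_pos,
                }
            )
        summary = summary.merge(pd.DataFrame(rows), on=["condition", "replicate_id"], how="left")

    return QuantifyResult(summary=summary, tss=tss, i1=i1_by_probe)
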