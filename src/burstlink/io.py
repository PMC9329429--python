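"""Dataset container and CSV readers/writers.

A dataset is two (optionally three) CSV tables:

* ``cells.csv`` — ``cell_id, replicate_id, condition, nx, ny, nz,
  nucleus_radius``: one row per segmented cell with the nucleus centre (um)
  and radius.
* ``spots.csv`` — ``spot_id, cell_id, probe_id, channel, x, y, z,
  intensity, compartment``: one row per detected fluorescent spot;
  positions in um, integrated intensity in arbitrary units, compartment in
  {nuclear, cytoplasmic}.
* ``truth.csv`` (optional) — per-allele generative ground truth emitted by
  the simulator; absent for real data.

Files are UTF-8 with a header row and RFC-4180 quoting; rows are sorted by
their ids so two writes of the same dataset are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from burstlink.errors import IntegrityError, SchemaError

__all__ = ["Dataset", "load_dataset", "write_dataset", "CELL_COLUMNS", "SPOT_COLUMNS"]

CELL_COLUMNS = ["cell_id", "replicate_id", "condition", "nx", "ny", "nz", "nucleus_radius"]
SPOT_COLUMNS = ["spot_id", "cell_id", "probe_id", "channel", "x", "y", "z", "intensity", "compartment"]

_FLOAT_FMT = "%.10g"  # round-trips to >= 9 significant digits


@dataclass
class Dataset:
    """In-memory dataset: cells and spots tables plus optional ground truth."""

    cells: pd.DataFrame
    spots: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None)

    def validate(self) -> "Dataset":
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise SchemaError(f"cells table is missing required column {col!r}")
        for col in SPOT_COLUMNS:
            if col not in self.spots.columns:
                raise SchemaError(f"spots table is missing required column {col!r}")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells.loc[self.cells["cell_id"].duplicated(), "cell_id"].tolist()
            raise IntegrityError(f"duplicate cell_id values: {dup[:10]}")
        if self.spots["spot_id"].duplicated().any():
            dup = self.spots.loc[self.spots["spot_id"].duplicated(), "spot_id"].tolist()
            raise IntegrityError(f"duplicate spot_id values: {dup[:10]}")
        known = set(self.cells["cell_id"])
        orphan = set(self.spots["cell_id"]) - known
        if orphan:
            raise IntegrityError(
                f"spots reference cell_id values absent from the cells table: {sorted(orphan)[:10]}"
            )
        if (self.spots["intensity"] < 0).any():
            raise SchemaError("spot intensity must be >= 0")
        if (self.cells["nucleus_radius"] <= 0).any():
            raise SchemaError("nucleus_radius must be > 0")
        bad = set(self.spots["compartment"]) - {"nuclear", "cytoplasmic"}
        if bad:
            raise SchemaError(f"unknown compartment labels: {sorted(bad)}")
        if self.truth is not None:
            t_orphan = set(self.truth["cell_id"]) - known
            if t_orphan:
                raise IntegrityError(
                    f"truth references unknown cell_id values: {sorted(t_orphan)[:10]}"
                )
        return self

    def subset_condition(self, condition: str) -> "Dataset":
        cells = self.cells[self.cells["condition"] == condition]
        spots = self.spots[self.spots["cell_id"].isin(cells["cell_id"])]
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["cell_id"].isin(cells["cell_id"])]
        return Dataset(cells.reset_index(drop=True), spots.reset_index(drop=True), truth)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``cells.csv``/``spots.csv`` (and ``truth.csv`` if present).

    Deterministic: rows sorted by ids, fixed column order, floats at 10
    significant digits.  Returns the written paths keyed by table name.
    """
    dataset.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cells = dataset.cells[CELL_COLUMNS].sort_values("cell_id", kind="mergesort")
    paths["cells"] = out / "cells.csv"
    cells.to_csv(paths["cells"], index=False, float_format=_FLOAT_FMT)

    spots = dataset.spots[SPOT_COLUMNS].sort_values("spot_id", kind="mergesort")
    paths["spots"] = out / "spots.csv"
    spots.to_csv(paths["spots"], index=False, float_format=_FLOAT_FMT)

    if dataset.truth is not None:
        truth = dataset.truth.sort_values(
            [c for c in ("cell_id", "allele") if c in dataset.truth.columns],
            kind="mergesort",
        )
        paths["truth"] = out / "truth.csv"
        truth.to_csv(paths["truth"], index=False, float_format=_FLOAT_FMT)
    return paths


def load_dataset(
    cells_path: str | Path,
    spots_path: str | Path,
    truth_path: str | Path | None = None,
) -> Dataset:
    """Load and validate a dataset from CSV files.

    Raises :class:`SchemaError` for missing columns and
    :class:`IntegrityError` for spots referencing unknown cells.
    """
    cells = pd.read_csv(cells_path)
    spots = pd.read_csv(spots_path)
    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path)
    return Dataset(cells=cells, spots=spots, truth=truth).validate()


def load_dataset_dir(directory: str | Path) -> Dataset:
    """Load ``cells.csv``/``spots.csv``/``truth.csv`` from one directory."""
    d = Path(directory)
    truth = d / "truth.csv"
    return load_dataset(d / "cells.csv", d / "spots.csv", truth if truth.exists() else None)
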