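"""Spatial grid assignment and per-cell median day-of-year estimates.

Observations are binned into square cells (default 10 x 10 km) on an
abstract planar grid; within each (cell, species, stage, year) group the
median DOY is the cell estimate. A cell with a single observation uses
that observation's DOY; even-sized groups use the midpoint of the two
central values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "assign_grid_cells", "cell_median_doy", "shared_cells"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Planar grid: origin, cell size, extent in cells (half-open cells)."""

    x0: float = 0.0
    y0: float = 0.0
    cell_width: float = 10.0
    cell_height: float = 10.0
    nx: int | None = None  # None: unbounded extent
    ny: int | None = None

    def __post_init__(self) -> None:
        if self.cell_width <= 0 or self.cell_height <= 0:
            raise ValueError("cell width/height must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GridSpec":
        return cls(**json.loads(Path(path).read_text()))


def assign_grid_cells(
    records: pd.DataFrame, grid: GridSpec, x_col: str = "x", y_col: str = "y"
) -> pd.DataFrame:
    """Add ``cell_i``/``cell_j`` columns: floor((coord - origin) / size).

    Cells are half-open ``[edge, edge + w)``; every in-extent point maps
    to exactly one cell. Out-of-extent records raise, listing their ids.
    """
    df = records.copy()
    ci = np.floor((df[x_col].to_numpy(float) - grid.x0) / grid.cell_width).astype(int)
    cj = np.floor((df[y_col].to_numpy(float) - grid.y0) / grid.cell_height).astype(int)
    bad = (ci < 0) | (cj < 0)
    if grid.nx is not None:
        bad |= ci >= grid.nx
    if grid.ny is not None:
        bad |= cj >= grid.ny
    if bad.any():
        ids = df.loc[bad, "id"].astype(str).tolist() if "id" in df else list(np.flatnonzero(bad))
        raise ValueError(f"records outside grid extent: {', '.join(map(str, ids[:10]))}")
    df["cell_i"] = ci
    df["cell_j"] = cj
    return df


def cell_median_doy(
    records: pd.DataFrame,
    species_col: str = "predicted_species",
    stage_col: str = "predicted_stage",
) -> pd.DataFrame:
    """Median DOY per (cell, species, stage, year) group with >= 1 record.

    Returns a cell-estimate table with columns
    ``cell_i, cell_j, species, stage, year, doy, n_obs``.
    """
    keys = ["cell_i", "cell_j", species_col, stage_col, "year"]
    out = (
        records.groupby(keys, sort=True)["doy"]
        .agg(doy="median", n_obs="size")
        .reset_index()
        .rename(columns={species_col: "species", stage_col: "stage"})
    )
    return out[["cell_i", "cell_j", "species", "stage", "year", "doy", "n_obs"]]


def shared_cells(
    a: pd.DataFrame,
    b: pd.DataFrame,
    require_all_years: bool = False,
    years: Sequence[int] | None = None,
) -> list[tuple[int, int]]:
    """Cells with estimates in both tables (optionally in every year).

    Both tables are cell-estimate tables restricted to one
    (species, stage). With ``require_all_years``, a cell qualifies only if
    each source covers it in every year of ``years`` (default: the union
    of years present in either table).
    """
    def cells_of(df: pd.DataFrame) -> set[tuple[int, int]]:
        if not require_all_years:
            return set(map(tuple, df[["cell_i", "cell_j"]].itertuples(index=False)))
        yrs = set(years) if years is not None else set(a["year"]) | set(b["year"])
        per_cell = df.groupby(["cell_i", "cell_j"])["year"].agg(set)
        return {c for c, ys in per_cell.items() if yrs <= ys}

    common = cells_of(a) & cells_of(b)
    if not common:
        logger.warning("shared_cells: no cells shared between the two sources")
    return sorted(common)
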