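"""Correspondence between opportunistic and systematic phenology estimates.

Because systematic networks record stage *onset* while opportunistic data
are summarized by the *median observation date*, the two levels are not
directly comparable — the median always lags the onset. Correspondence is
therefore assessed on structure that is invariant to a constant lag:

* interannual differences — per-cell DOY differences between consecutive
  years, computed within each source;
* simple Mantel tests — the Pearson correlation r_M between the
  (Euclidean) distance matrices of the two sources' cell DOYs over shared
  cells, with a one-tailed permutation test (default 9,999 permutations,
  large positive r_M extreme) obtained by jointly shuffling rows and
  columns of one matrix.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .grid import shared_cells
from .scheme import SYSTEMATIC_STAGES, Stage

__all__ = [
    "DifferenceSummary",
    "MantelResult",
    "interannual_differences",
    "euclidean_distance_matrix",
    "mantel_test",
    "run_comparison",
    "ComparisonReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DifferenceSummary:
    """Per-cell DOY differences between two years for one species-stage."""

    species: str
    stage: str
    year_a: int
    year_b: int
    differences: dict[tuple[int, int], float]  # cell -> doy(b) - doy(a)
    median: float
    q1: float
    q3: float

    @property
    def n_cells(self) -> int:
        return len(self.differences)


def interannual_differences(
    estimates: pd.DataFrame, year_a: int, year_b: int
) -> DifferenceSummary:
    """Per-cell difference doy(year_b) - doy(year_a) over shared cells.

    ``estimates`` is a cell-estimate table for a single (species, stage).

    Raises
    ------
    ValueError
        If the table mixes species/stages or the years share no cell.
    """
    for col in ("species", "stage"):
        if estimates[col].nunique() > 1:
            raise ValueError(f"estimates mix several values of {col!r}")
    piv = estimates.pivot_table(index=["cell_i", "cell_j"], columns="year", values="doy")
    if year_a not in piv.columns or year_b not in piv.columns:
        raise ValueError(f"no estimates for year {year_a} or {year_b}")
    both = piv[[year_a, year_b]].dropna()
    if len(both) == 0:
        raise ValueError(f"no cells shared between {year_a} and {year_b}")
    diffs = (both[year_b] - both[year_a]).to_dict()
    vals = np.array(list(diffs.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return DifferenceSummary(
        species=str(estimates["species"].iloc[0]),
        stage=str(estimates["stage"].iloc[0]),
        year_a=year_a,
        year_b=year_b,
        differences={k: float(v) for k, v in diffs.items()},
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def euclidean_distance_matrix(values: Sequence[float]) -> np.ndarray:
    """Euclidean distance matrix |v_i - v_j| of an ordered scalar vector.

    Requires at least 3 entries (a Mantel test on fewer is not useful).
    """
    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(v) < 3:
        raise ValueError("need at least 3 cells for a distance matrix")
    return squareform(pdist(v, metric="euclidean"))


@dataclass(frozen=True)
class MantelResult:
    """Simple Mantel correlation with one-tailed permutation significance.

    ``r_m`` is the Pearson correlation of the strictly-upper-triangle
    entries of the two distance matrices; ``p_value`` is the one-tailed
    (greater) permutation p, ``(1 + #{r_perm >= r_obs}) / (1 + n_perm)``,
    so it is never below ``1 / (n_perm + 1)``. ``undefined`` flags a
    degenerate input (zero variance in a triangle); then ``r_m`` and
    ``p_value`` are NaN.
    """

    r_m: float
    p_value: float
    n_permutations: int
    n_cells: int
    seed: int | None = None
    undefined: bool = False

    @property
    def stars(self) -> str:
        if self.undefined or math.isnan(self.p_value):
            return ""
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < thr:
                return s
        return "ns"


def _triu_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """Simple Mantel test between two distance matrices.

    The null distribution is built by applying a random permutation
    jointly to the rows and columns of ``d2`` and recomputing the
    upper-triangle correlation. With ``exact=True`` all n! permutations
    are enumerated (n <= 8) and the p-value is the exact fraction of
    permutations (identity included) with ``r_perm >= r_obs``.

    Raises
    ------
    ValueError
        On shape mismatch, non-square input, or n < 3.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 cells")
    iu = np.triu_indices(n, 1)
    v1 = d1[iu]
    v2 = d2[iu]
    if v1.std() == 0 or v2.std() == 0:
        return MantelResult(
            r_m=float("nan"), p_value=float("nan"),
            n_permutations=0, n_cells=n, seed=seed, undefined=True,
        )
    r_obs = _triu_pearson(v1, v2)
    eps = 1e-12

    if exact:
        if n > 8:
            raise ValueError("exact enumeration supported for n <= 8")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r = _triu_pearson(v1, d2[np.ix_(p, p)][iu])
            count += r >= r_obs - eps
            total += 1
        return MantelResult(
            r_m=r_obs, p_value=count / total,
            n_permutations=total, n_cells=n, seed=None,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = _triu_pearson(v1, d2[np.ix_(p, p)][iu])
        count += r >= r_obs - eps
    p_value = (1 + count) / (1 + n_perm)
    return MantelResult(
        r_m=r_obs, p_value=p_value, n_permutations=n_perm, n_cells=n, seed=seed
    )


@dataclass
class ComparisonReport:
    """Mantel correspondence per (species, stage, year) plus interannual
    difference summaries per source and consecutive-year pair."""

    mantel: pd.DataFrame  # species, stage, year, n_cells, r_m, p_value, signif
    differences: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mantel": self.mantel.to_dict(orient="records"),
            "differences": self.differences,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.mantel.to_csv(path, index=False)


def run_comparison(
    opportunistic: pd.DataFrame,
    systematic: pd.DataFrame,
    years: Sequence[int] | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    stages: Sequence[Stage] = SYSTEMATIC_STAGES,
) -> ComparisonReport:
    """Full correspondence analysis between two cell-estimate tables.

    For each (species, comparable stage, year): the Mantel test over the
    cells shared by both sources in that year. For each consecutive year
    pair and each source: the per-cell interannual difference summary over
    that source's all-years cells. Missing combinations are reported as
    absent rather than raising.
    """
    stage_vals = {Stage(s).value for s in stages}
    if years is None:
        years = sorted(set(opportunistic["year"]) | set(systematic["year"]))
    years = list(years)
    rows = []
    diffs: list[dict] = []
    species = sorted(set(opportunistic["species"]) | set(systematic["species"]))
    rng = np.random.default_rng(seed)
    for sp in species:
        for st in sorted(stage_vals):
            opp = opportunistic[(opportunistic["species"] == sp) & (opportunistic["stage"] == st)]
            sys = systematic[(systematic["species"] == sp) & (systematic["stage"] == st)]
            if opp.empty or sys.empty:
                continue
            for year in years:
                o = opp[opp["year"] == year].set_index(["cell_i", "cell_j"])["doy"]
                s = sys[sys["year"] == year].set_index(["cell_i", "cell_j"])["doy"]
                cells = shared_cells(
                    opp[opp["year"] == year], sys[sys["year"] == year]
                )
                if len(cells) < 3:
                    rows.append(
                        dict(species=sp, stage=st, year=year, n_cells=len(cells),
                             r_m=float("nan"), p_value=float("nan"), signif="")
                    )
                    continue
                # duplicate-safe: one estimate per cell by construction
                vo = o.loc[cells].to_numpy(float)
                vs = s.loc[cells].to_numpy(float)
                res = mantel_test(
                    euclidean_distance_matrix(vo),
                    euclidean_distance_matrix(vs),
                    n_perm=n_perm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                rows.append(
                    dict(species=sp, stage=st, year=year, n_cells=res.n_cells,
                         r_m=res.r_m, p_value=res.p_value, signif=res.stars)
                )
            for ya, yb in zip(years, years[1:]):
                for name, est in (("opportunistic", opp), ("systematic", sys)):
                    all_years_cells = shared_cells(est, est, require_all_years=True, years=years)
                    sub = est.set_index(["cell_i", "cell_j"]).loc[
                        est.set_index(["cell_i", "cell_j"]).index.isin(all_years_cells)
                    ].reset_index()
                    try:
                        summ = interannual_differences(sub, ya, yb)
                    except ValueError:
                        continue
                    diffs.append(
                        dict(source=name, species=sp, stage=st, year_a=ya, year_b=yb,
                             n_cells=summ.n_cells, median=summ.median,
                             q1=summ.q1, q3=summ.q3)
                    )
    mantel_df = pd.DataFrame(
        rows, columns=["species", "stage", "year", "n_cells", "r_m", "p_value", "signif"]
    )
    return ComparisonReport(mantel=mantel_df, differences=diffs)
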