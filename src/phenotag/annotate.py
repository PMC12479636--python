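"""Annotation of opportunistic records and temporal outlier filtering.

The trained classifier assigns each observation a (species, stage) label
from its feature vector; vegetative records are then excluded (the label
covers all non-reproductive phases and is not a distinct phenophase), and
temporal outliers are removed per species-phenostage-year group by the
1.5 x IQR rule: a record is dropped when its day of year lies strictly
beyond [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of its group. Quartiles use linear
interpolation between order statistics. The filter is single-pass;
re-filtering the kept records may remove more and is deliberately not done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import PhenostageClassifier, predict, split_label
from .scheme import Stage
from .simulate import ObservationSet

__all__ = [
    "OutlierBounds",
    "annotate_observations",
    "drop_vegetative",
    "iqr_bounds",
    "filter_outliers",
]

logger = logging.getLogger(__name__)

#: Groups smaller than this pass through the outlier filter unfiltered:
#: quartile estimates on a handful of records are too unstable to act on.
MIN_GROUP_SIZE = 4


def annotate_observations(
    clf: PhenostageClassifier, obs: ObservationSet
) -> pd.DataFrame:
    """Predict a (species, stage) label for every observation.

    Returns the records table with ``predicted_species`` and
    ``predicted_stage`` columns added; the record count is preserved.

    Raises
    ------
    ValueError
        If the observation set carries no feature matrix, or rows contain
        non-finite features (listing the offending record ids).
    """
    df = obs.records.copy()
    if obs.features is None:
        raise ValueError("observation set has no feature vectors to annotate")
    bad = np.flatnonzero(~np.isfinite(obs.features).all(axis=1))
    if bad.size:
        ids = ", ".join(df["id"].iloc[bad[:10]].astype(str))
        raise ValueError(f"records with missing/non-finite features: {ids}")
    labels = predict(clf, obs.features)
    pairs = [split_label(lab) for lab in labels]
    df["predicted_species"] = [sp for sp, _ in pairs]
    df["predicted_stage"] = [st.value for _, st in pairs]
    return df


def drop_vegetative(annotated: pd.DataFrame, stage_col: str = "predicted_stage") -> pd.DataFrame:
    """Remove vegetative records; all others pass through in order."""
    out = annotated[annotated[stage_col] != Stage.VEGETATIVE.value]
    if len(out) == 0 and len(annotated) > 0:
        logger.warning("drop_vegetative: all %d records were vegetative", len(annotated))
    return out.copy()


@dataclass(frozen=True)
class OutlierBounds:
    """Quartiles and the 1.5 x IQR exclusion bounds of a DOY group."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr

    def is_outlier(self, doy: np.ndarray) -> np.ndarray:
        """Strictly beyond the bounds; values exactly at a bound are kept."""
        doy = np.asarray(doy, dtype=float)
        return (doy < self.lower) | (doy > self.upper)


def iqr_bounds(doys: Sequence[float]) -> OutlierBounds:
    """Quartiles (linear interpolation) and 1.5 x IQR bounds of a group."""
    doys = np.asarray(doys, dtype=float)
    if doys.size == 0:
        raise ValueError("iqr_bounds: empty group")
    q1, q3 = np.percentile(doys, [25, 75])
    return OutlierBounds(q1=float(q1), q3=float(q3))


def filter_outliers(
    annotated: pd.DataFrame,
    group_keys: Sequence[str] = ("predicted_species", "predicted_stage", "year"),
    doy_col: str = "doy",
    min_group_size: int = MIN_GROUP_SIZE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass 1.5 x IQR outlier removal per group.

    Returns ``(kept, removed)``; the two partition the input. ``removed``
    carries the group bounds (``q1, q3, lower, upper``) for audit. Groups
    smaller than ``min_group_size`` pass through unfiltered.
    """
    if len(annotated) == 0:
        return annotated.copy(), annotated.copy()
    kept_parts, removed_parts = [], []
    for key, grp in annotated.groupby(list(group_keys), sort=False):
        if len(grp) < min_group_size:
            kept_parts.append(grp)
            continue
        b = iqr_bounds(grp[doy_col])
        mask = b.is_outlier(grp[doy_col].to_numpy())
        kept_parts.append(grp[~mask])
        rem = grp[mask].copy()
        if len(rem):
            rem["q1"], rem["q3"] = b.q1, b.q3
            rem["lower"], rem["upper"] = b.lower, b.upper
            removed_parts.append(rem)
    kept = pd.concat(kept_parts).sort_index() if kept_parts else annotated.iloc[0:0].copy()
    if removed_parts:
        removed = pd.concat(removed_parts).sort_index()
    else:
        removed = annotated.iloc[0:0].copy()
        for c in ("q1", "q3", "lower", "upper"):
            removed[c] = pd.Series(dtype=float)
    logger.info(
        "filter_outliers: %d in, %d kept, %d removed", len(annotated), len(kept), len(removed)
    )
    return kept, removed
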