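"""CSV/JSON input-output with validation and reproducibility headers.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimals. Files written by the pipeline start with ``#``-prefixed comment
lines embedding the global seed and a hash of the configuration, so reruns
are auditable; readers skip those lines. Feature vectors travel in a
sidecar matrix CSV (column ``id`` plus ``f0..f{d-1}``) referenced by
record id.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import pandas as pd

from .classify import LabeledFeatureSet, PhenostageClassifier
from .scheme import PhenostageScheme, Stage
from .simulate import ObservationSet

__all__ = [
    "write_table",
    "read_table",
    "write_observations",
    "read_observations",
    "write_onsets",
    "read_onsets",
    "write_feature_set",
    "read_feature_set",
    "save_classifier",
    "load_classifier",
]

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["id", "species", "stage_true", "year", "date", "doy", "x", "y", "is_outlier"]
ONSET_COLUMNS = ["site_id", "species", "stage", "year", "x", "y", "doy"]


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a CSV with optional ``# key: value`` header comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, checking required columns."""
    df = pd.read_csv(path, comment="#")
    for col in required or []:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def _parse_dates(df: pd.DataFrame, path: Path) -> pd.Series:
    """ISO-8601 date parsing with row numbers in errors (1-based, data rows)."""
    out = []
    for row, s in enumerate(df["date"].astype(str), start=2):
        try:
            out.append(_dt.date.fromisoformat(s))
        except ValueError as exc:
            raise ValueError(f"{path}, row {row}: invalid date {s!r}: {exc}") from None
    return pd.Series(out, index=df.index)


def write_observations(
    obs: ObservationSet,
    path: str | Path,
    features_path: str | Path | None = None,
    meta: Mapping[str, object] | None = None,
) -> None:
    write_table(obs.records[OBS_COLUMNS], path, meta)
    if features_path is not None:
        if obs.features is None:
            raise ValueError("observation set has no features to write")
        _write_matrix(obs.records["id"], obs.features, features_path, meta)


def read_observations(
    path: str | Path,
    scheme: PhenostageScheme | None = None,
    features_path: str | Path | None = None,
) -> ObservationSet:
    """Read observations; validates dates, derived DOY and species names."""
    path = Path(path)
    df = read_table(path, required=[c for c in OBS_COLUMNS if c != "stage_true"])
    dates = _parse_dates(df, path)
    derived = np.array([d.timetuple().tm_yday for d in dates])
    if not np.array_equal(derived, df["doy"].to_numpy(int)):
        bad = df.loc[derived != df["doy"].to_numpy(int), "id"].astype(str).tolist()
        raise ValueError(f"{path}: doy inconsistent with date for: {', '.join(bad[:10])}")
    if scheme is not None:
        for sp in pd.unique(df["species"]):
            scheme.resolve_species(sp)  # raises KeyError naming the species
    features = None
    if features_path is not None:
        features = _read_matrix(features_path, df["id"])
    return ObservationSet(records=df, features=features)


def write_onsets(onsets: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    write_table(onsets[ONSET_COLUMNS], path, meta)


def read_onsets(path: str | Path, scheme: PhenostageScheme | None = None) -> pd.DataFrame:
    df = read_table(Path(path), required=ONSET_COLUMNS)
    if scheme is not None:
        for sp in pd.unique(df["species"]):
            scheme.resolve_species(sp)
        for st in pd.unique(df["stage"]):
            Stage(st)
    return df


def _write_matrix(ids: pd.Series, X: np.ndarray, path: str | Path, meta=None) -> None:
    mat = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    mat.insert(0, "id", ids.to_numpy())
    write_table(mat, path, meta)


def _read_matrix(path: str | Path, ids: pd.Series) -> np.ndarray:
    mat = read_table(path, required=["id"])
    mat = mat.set_index("id").loc[ids.to_numpy()]
    return mat.to_numpy(dtype=float)


def write_feature_set(
    data: LabeledFeatureSet,
    labels_path: str | Path,
    matrix_path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    lab = pd.DataFrame({"id": data.ids, "species": data.species, "stage": data.stage})
    write_table(lab, labels_path, meta)
    _write_matrix(lab["id"], data.X, matrix_path, meta)


def read_feature_set(labels_path: str | Path, matrix_path: str | Path) -> LabeledFeatureSet:
    lab = read_table(labels_path, required=["id", "species", "stage"])
    X = _read_matrix(matrix_path, lab["id"])
    return LabeledFeatureSet(
        ids=lab["id"].to_numpy(), X=X,
        species=lab["species"].to_numpy(object),
        stage=lab["stage"].to_numpy(object),
    )


def save_classifier(clf: PhenostageClassifier, path: str | Path) -> None:
    joblib.dump(clf, path)


def load_classifier(path: str | Path) -> PhenostageClassifier:
    return joblib.load(path)
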