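"""Synthetic data with the statistical structure the pipeline assumes.

Three generators stand in for the study's data streams:

* :func:`generate_feature_dataset` — labeled deep-feature stand-ins: one
  isotropic Gaussian cluster per (species, stage) class.
* :func:`sample_opportunistic_observations` — app-style records (date,
  location, feature vector) drawn from a latent phenology field, with
  population-density bias, a configurable fraction of vegetative images,
  and planted temporal outliers.
* :func:`sample_systematic_onsets` — protocol-style onset records that lead
  the opportunistic median date by a configurable number of days.

The latent field gives every (species, stage, year, cell) a true mean
day-of-year: a stage baseline, plus a species offset, a year effect, a
linear spatial gradient (a latitude/elevation proxy), and a cell-level
site effect shared across stages of a species, so that stage order is
preserved in every cell by construction. All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import LabeledFeatureSet, class_label
from .scheme import (
    STAGE_RANK,
    SYSTEMATIC_STAGES,
    PhenostageScheme,
    Stage,
    build_default_scheme,
    load_reference_metrics,
)

__all__ = [
    "FeatureSimConfig",
    "ClassClusterModel",
    "generate_feature_dataset",
    "PhenologyFieldConfig",
    "PhenologyField",
    "ObservationSet",
    "sample_opportunistic_observations",
    "sample_systematic_onsets",
    "render_toy_specimen",
]


# ---------------------------------------------------------------------------
# Feature clusters


@dataclass(frozen=True)
class FeatureSimConfig:
    """Configuration of the per-class feature clusters.

    ``dim`` defaults to 1792, the length of the deep-feature vectors the
    real extractor produces. ``centroid_scale`` is the s.d. of centroid
    coordinates, ``spread`` the within-class s.d.; their ratio (default 6)
    controls class separability. ``class_sizes`` defaults to the reference
    table's train+test counts per class.
    """

    dim: int = 1792
    centroid_scale: float = 6.0
    spread: float = 1.0
    class_sizes: Mapping[tuple[str, Stage], int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.centroid_scale < 0:
            raise ValueError("centroid dispersion must be >= 0")
        if self.class_sizes is not None:
            for k, v in self.class_sizes.items():
                if v < 1:
                    raise ValueError(f"class size must be >= 1 (got {v} for {k})")


def _default_class_sizes(scheme: PhenostageScheme) -> dict[tuple[str, Stage], int]:
    ref = load_reference_metrics()
    sizes = {
        (r.species, Stage(r.stage)): int(r.train_n + r.test_n)
        for r in ref.itertuples()
    }
    return {c: sizes[c] for c in scheme.classes}


class ClassClusterModel:
    """Fixed class centroids; samples features around them.

    Centroids are drawn once from ``N(0, centroid_scale^2 I)`` per class
    (in scheme order, from the config seed) so that feature sets and
    observation features generated from the same config live in the same
    feature space.
    """

    def __init__(self, scheme: PhenostageScheme, cfg: FeatureSimConfig):
        self.scheme = scheme
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.centroids: dict[tuple[str, Stage], np.ndarray] = {
            cls: rng.normal(0.0, cfg.centroid_scale, cfg.dim)
            for cls in scheme.classes
        }

    def sample(
        self, cls: tuple[str, Stage], n: int, rng: np.random.Generator
    ) -> np.ndarray:
        if cls not in self.centroids:
            raise KeyError(f"class not in scheme: {cls}")
        c = self.centroids[cls]
        return c + rng.normal(0.0, self.cfg.spread, (n, self.cfg.dim))


def generate_feature_dataset(
    cfg: FeatureSimConfig, scheme: PhenostageScheme | None = None
) -> LabeledFeatureSet:
    """Generate a labeled feature set: one Gaussian cluster per class.

    Class sizes are exactly as configured; output is bit-identical for a
    fixed config (the sampling order is the scheme's class order).
    """
    scheme = scheme or build_default_scheme()
    sizes = dict(cfg.class_sizes) if cfg.class_sizes is not None else _default_class_sizes(scheme)
    for cls in sizes:
        sp, st = cls
        if not scheme.has_class(sp, st):
            raise ValueError(f"class in sizes but not in scheme: {cls}")
    clusters = ClassClusterModel(scheme, cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    ids, X, species, stage = [], [], [], []
    for cls in scheme.classes:
        if cls not in sizes:
            continue
        n = sizes[cls]
        X.append(clusters.sample(cls, n, rng))
        sp, st = cls
        species.extend([sp] * n)
        stage.extend([st.value] * n)
        ids.extend(f"{class_label(sp, st)}-{k}" for k in range(n))
    return LabeledFeatureSet(
        ids=np.array(ids), X=np.vstack(X),
        species=np.array(species, dtype=object),
        stage=np.array(stage, dtype=object),
    )


# ---------------------------------------------------------------------------
# Latent phenology field

#: Default stage baseline mean DOYs (northern temperate woody species):
#: seedling germination in early spring, flowering buds before flowering,
#: fruit ripening through late summer, senescence in autumn.
DEFAULT_STAGE_BASELINES: dict[Stage, float] = {
    Stage.SEEDLING: 95.0,
    Stage.FLOWERING_BUD: 105.0,
    Stage.FLOWERING: 125.0,
    Stage.UNRIPE_FRUIT: 165.0,
    Stage.FRUIT: 175.0,
    Stage.RIPE_FRUIT: 215.0,
    Stage.SENESCENCE: 285.0,
}


@dataclass(frozen=True)
class PhenologyFieldConfig:
    """Latent spatiotemporal phenology field over a planar km grid.

    ``gradient_days_per_km`` shifts true DOYs linearly along
    ``gradient_axis`` (a latitude/elevation proxy). ``cell_noise_sd`` is
    the s.d. of the per-(species, year, cell) site effect;
    ``obs_noise_sd`` the within-cell observation scatter.
    ``onset_lead_days`` is how many days the systematic onset precedes the
    local true mean (hence the opportunistic median) of the same stage.
    """

    width_km: float = 100.0
    height_km: float = 100.0
    cell_km: float = 10.0
    years: tuple[int, ...] = (2020, 2021, 2022)
    year_effects: Mapping[int, float] | None = None
    gradient_days_per_km: float = 0.3
    gradient_axis: str = "y"
    cell_noise_sd: float = 2.0
    obs_noise_sd: float = 3.0
    onset_lead_days: float = 7.0
    stage_baselines: Mapping[Stage, float] | None = None
    species_offset_step: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_km <= 0 or self.width_km <= 0 or self.height_km <= 0:
            raise ValueError("domain extent and cell size must be positive")
        if len(self.years) == 0:
            raise ValueError("at least one year is required")
        if self.gradient_axis not in ("x", "y"):
            raise ValueError("gradient_axis must be 'x' or 'y'")
        base = self.resolved_baselines()
        ranked = sorted(base, key=STAGE_RANK.__getitem__)
        for a, b in zip(ranked, ranked[1:]):
            if base[a] >= base[b]:
                raise ValueError(
                    f"stage baselines must respect phenological order: {a} >= {b}"
                )

    def resolved_baselines(self) -> dict[Stage, float]:
        base = dict(DEFAULT_STAGE_BASELINES)
        if self.stage_baselines:
            base.update({Stage(k): float(v) for k, v in self.stage_baselines.items()})
        return base

    def resolved_year_effects(self) -> dict[int, float]:
        if self.year_effects is None:
            defaults = {2020: 0.0, 2021: 10.0, 2022: 2.0}
            return {y: defaults.get(y, 0.0) for y in self.years}
        return {y: float(self.year_effects.get(y, 0.0)) for y in self.years}


class PhenologyField:
    """Realized latent field: true mean DOY per (species, stage, year, cell)."""

    def __init__(
        self, cfg: PhenologyFieldConfig, scheme: PhenostageScheme | None = None
    ):
        self.cfg = cfg
        self.scheme = scheme or build_default_scheme()
        self.nx = int(round(cfg.width_km / cfg.cell_km))
        self.ny = int(round(cfg.height_km / cfg.cell_km))
        if self.nx < 1 or self.ny < 1:
            raise ValueError("domain must contain at least one cell")
        self._species = list(self.scheme.species)
        self._sp_idx = {sp: i for i, sp in enumerate(self._species)}
        self._years = list(cfg.years)
        self._yr_idx = {y: i for i, y in enumerate(self._years)}
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
        # site effect shared across stages of a species-year
        self._cell_eff = rng.normal(
            0.0, cfg.cell_noise_sd, (len(self._species), len(self._years), self.nx, self.ny)
        )
        cx = (np.arange(self.nx) + 0.5) * cfg.cell_km
        cy = (np.arange(self.ny) + 0.5) * cfg.cell_km
        if cfg.gradient_axis == "y":
            coord = np.broadcast_to(cy[None, :], (self.nx, self.ny))
            mid = cfg.height_km / 2.0
        else:
            coord = np.broadcast_to(cx[:, None], (self.nx, self.ny))
            mid = cfg.width_km / 2.0
        self._gradient = cfg.gradient_days_per_km * (coord - mid)
        self._baselines = cfg.resolved_baselines()
        self._year_effects = cfg.resolved_year_effects()

    @property
    def years(self) -> list[int]:
        return list(self._years)

    def baseline(self, species: str, stage: Stage) -> float:
        sp = self.scheme.resolve_species(species)
        if Stage(stage) not in self.scheme.stages_by_species[sp]:
            raise KeyError(f"({species}, {stage}) not in scheme")
        return self._baselines[Stage(stage)] + self._sp_idx[sp] * self.cfg.species_offset_step

    def mean_grid(self, species: str, stage: Stage, year: int) -> np.ndarray:
        """True mean DOY over the (nx, ny) cell grid."""
        sp = self.scheme.resolve_species(species)
        base = self.baseline(sp, stage)
        return (
            base
            + self._year_effects[year]
            + self._gradient
            + self._cell_eff[self._sp_idx[sp], self._yr_idx[year]]
        )

    def cell_mean(self, species: str, stage: Stage, year: int, i: int, j: int) -> float:
        return float(self.mean_grid(species, stage, year)[i, j])

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        return int(np.floor(x / self.cfg.cell_km)), int(np.floor(y / self.cfg.cell_km))

    def cell_centers(self) -> np.ndarray:
        """(nx*ny, 2) array of cell-center coordinates."""
        cx = (np.arange(self.nx) + 0.5) * self.cfg.cell_km
        cy = (np.arange(self.ny) + 0.5) * self.cfg.cell_km
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])


# ---------------------------------------------------------------------------
# Observation sampling


@dataclass
class ObservationSet:
    """Opportunistic records plus (optionally) their feature vectors.

    ``records`` columns: id, species, stage_true, year, date, doy, x, y,
    is_outlier. ``features`` is row-aligned with ``records`` when present.
    ``stage_true`` and ``is_outlier`` are generation truth that the
    pipeline itself never reads; they exist for validation.
    """

    records: pd.DataFrame
    features: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)


def _doy_to_date(year: int, doy: int) -> _dt.date:
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy) - 1)


def _days_in_year(year: int) -> int:
    return 366 if _dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365


def _finalize_doy(doy: np.ndarray, year: int) -> np.ndarray:
    return np.clip(np.rint(doy), 1, _days_in_year(year)).astype(int)


def sample_opportunistic_observations(
    field: PhenologyField,
    feat_cfg: FeatureSimConfig | None = None,
    intensity: float = 2.0,
    bias: np.ndarray | None = None,
    outlier_rate: float = 0.0,
    vegetative_fraction: float = 0.5,
    seed: int = 0,
    species: Sequence[str] | None = None,
    stages: Sequence[Stage] | None = None,
) -> ObservationSet:
    """Sample app-style opportunistic observations from the latent field.

    Per cell, class and year the record count is Poisson with rate
    ``intensity * bias[i, j]`` (``bias`` defaults to a uniform map; a
    population-density multiplier). DOYs scatter around the cell truth
    with ``obs_noise_sd``. A fraction ``outlier_rate`` of each
    (species, stage, year) group is displaced from the group median by
    well over 4x the group IQR (direction chosen toward the calendar side
    with room). Vegetative records are drawn uniformly over DOY 60-330.
    Features, when ``feat_cfg`` is given, come from the record's true
    class cluster.
    """
    cfg = field.cfg
    if not 0 <= outlier_rate < 1:
        raise ValueError("outlier_rate must be in [0, 1)")
    if not 0 <= vegetative_fraction < 1:
        raise ValueError("vegetative_fraction must be in [0, 1)")
    if bias is None:
        bias = np.ones((field.nx, field.ny))
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (field.nx, field.ny):
        raise ValueError(f"bias map must have shape {(field.nx, field.ny)}")

    scheme = field.scheme
    sp_filter = None if species is None else {scheme.resolve_species(s) for s in species}
    st_filter = None if stages is None else {Stage(s) for s in stages}
    classes = [
        (sp, st)
        for sp, st in scheme.classes
        if st in STAGE_RANK
        and (sp_filter is None or sp in sp_filter)
        and (st_filter is None or st in st_filter)
    ]
    if not classes:
        raise ValueError("no ranked classes selected")

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, seed, 11)))
    cell = cfg.cell_km
    frames: list[pd.DataFrame] = []
    for year in field.years:
        for sp, st in classes:
            counts = rng.poisson(intensity * bias)
            n = int(counts.sum())
            if n == 0:
                continue
            ii, jj = np.nonzero(counts)
            reps = counts[ii, jj]
            ii = np.repeat(ii, reps)
            jj = np.repeat(jj, reps)
            x = (ii + rng.uniform(0, 1, n)) * cell
            y = (jj + rng.uniform(0, 1, n)) * cell
            mu = field.mean_grid(sp, st, year)[ii, jj]
            doy = mu + rng.normal(0, cfg.obs_noise_sd, n)
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "stage_true": st.value,
                        "year": year,
                        "doy": doy,
                        "x": x,
                        "y": y,
                        "is_outlier": False,
                    }
                )
            )
    ranked = pd.concat(frames, ignore_index=True)

    # planted outliers, displaced per (species, stage, year) group
    if outlier_rate > 0:
        for _, idx in ranked.groupby(["species", "stage_true", "year"]).groups.items():
            idx = np.asarray(idx)
            k = int(np.floor(outlier_rate * len(idx)))
            if k == 0:
                continue
            doys = ranked.loc[idx, "doy"].to_numpy()
            q1, q3 = np.percentile(doys, [25, 75])
            delta = 5.0 * (q3 - q1) + 10.0
            med = np.median(doys)
            chosen = rng.choice(idx, size=k, replace=False)
            for r in chosen:
                up = med + delta <= 360
                ranked.loc[r, "doy"] = med + delta if up else med - delta
                ranked.loc[r, "is_outlier"] = True

    # vegetative records: uniform over a broad window, uniform in space
    veg_frames = []
    if vegetative_fraction > 0:
        per_species = ranked.groupby("species").size()
        for sp, n_sp in per_species.items():
            if Stage.VEGETATIVE not in scheme.stages_by_species[sp]:
                continue
            n_veg = int(round(vegetative_fraction / (1 - vegetative_fraction) * n_sp))
            if n_veg == 0:
                continue
            veg_frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "stage_true": Stage.VEGETATIVE.value,
                        "year": rng.choice(field.years, n_veg),
                        "doy": rng.uniform(60, 330, n_veg),
                        "x": rng.uniform(0, cfg.width_km, n_veg),
                        "y": rng.uniform(0, cfg.height_km, n_veg),
                        "is_outlier": False,
                    }
                )
            )
    df = pd.concat([ranked, *veg_frames], ignore_index=True)

    df["doy"] = [
        _finalize_doy(np.array([d]), y)[0] for d, y in zip(df["doy"], df["year"])
    ]
    df["date"] = [_doy_to_date(y, d).isoformat() for y, d in zip(df["year"], df["doy"])]
    df.insert(0, "id", [f"obs-{k:06d}" for k in range(len(df))])
    df = df[["id", "species", "stage_true", "year", "date", "doy", "x", "y", "is_outlier"]]

    features = None
    if feat_cfg is not None:
        clusters = ClassClusterModel(scheme, feat_cfg)
        features = np.empty((len(df), feat_cfg.dim))
        for (sp, st), idx in df.groupby(["species", "stage_true"]).groups.items():
            idx = np.asarray(idx)
            features[idx] = clusters.sample((sp, Stage(st)), len(idx), rng)
    return ObservationSet(records=df, features=features)


def sample_systematic_onsets(
    field: PhenologyField,
    sites: np.ndarray | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    species: Sequence[str] | None = None,
    stages: Sequence[Stage] | None = None,
) -> pd.DataFrame:
    """Sample protocol-style onset records at fixed sites.

    The onset of a stage at a site is the cell truth minus
    ``onset_lead_days`` plus observer noise: systematic networks record
    the first individual showing a stage, which precedes the median
    opportunistic observation date. One record per
    site x species x stage x year. ``sites`` defaults to every cell
    center; only stages a systematic network reports (flowering,
    ripe fruit, senescence) are generated.

    Columns: site_id, species, stage, year, x, y, doy.
    """
    cfg = field.cfg
    scheme = field.scheme
    if sites is None:
        sites = field.cell_centers()
    sites = np.asarray(sites, dtype=float)
    if sites.ndim != 2 or sites.shape[1] != 2:
        raise ValueError("sites must be an (n, 2) array of x, y")
    for x, y in sites:
        if not (0 <= x < cfg.width_km and 0 <= y < cfg.height_km):
            raise ValueError(f"site ({x}, {y}) outside domain")
    st_filter = set(SYSTEMATIC_STAGES if stages is None else (Stage(s) for s in stages))
    sp_filter = None if species is None else {scheme.resolve_species(s) for s in species}

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, seed, 13)))
    ii = np.floor(sites[:, 0] / cfg.cell_km).astype(int)
    jj = np.floor(sites[:, 1] / cfg.cell_km).astype(int)
    frames = []
    for sp, st in scheme.classes:
        if st not in st_filter or (sp_filter is not None and sp not in sp_filter):
            continue
        for year in field.years:
            mu = field.mean_grid(sp, st, year)[ii, jj]
            doy = mu - cfg.onset_lead_days + rng.normal(0, noise_sd, len(sites))
            frames.append(
                pd.DataFrame(
                    {
                        "site_id": [f"site-{k:04d}" for k in range(len(sites))],
                        "species": sp,
                        "stage": st.value,
                        "year": year,
                        "x": sites[:, 0],
                        "y": sites[:, 1],
                        "doy": _finalize_doy(doy, year),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Toy images (for the end-to-end image -> feature -> class demonstration)

_STAGE_COLOR = {
    Stage.SEEDLING: (170, 230, 140),
    Stage.FLOWERING_BUD: (210, 150, 190),
    Stage.FLOWERING: (250, 245, 250),
    Stage.UNRIPE_FRUIT: (60, 130, 60),
    Stage.FRUIT: (140, 100, 60),
    Stage.RIPE_FRUIT: (200, 40, 40),
    Stage.SENESCENCE: (230, 150, 40),
    Stage.VEGETATIVE: (70, 160, 70),
}


def render_toy_specimen(
    stage: Stage, species_idx: int, rng: np.random.Generator, size: int = 32
) -> np.ndarray:
    """Render a toy RGB "specimen": a stage-colored disk on foliage.

    Species identity is encoded in disk radius and background shade; stage
    in disk color. Deliberately simple, so the toy histogram extractor can
    separate the classes.
    """
    img = np.zeros((size, size, 3), dtype=float)
    bg = np.array([40 + 12 * (species_idx % 8), 120 + 8 * (species_idx % 5), 50.0])
    img[:] = bg + rng.normal(0, 6, (size, size, 3))
    r = 4 + (species_idx % 4) * 2
    cx, cy = rng.integers(r, size - r, 2)
    yy, xx = np.ogrid[:size, :size]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    img[mask] = np.array(_STAGE_COLOR[Stage(stage)], dtype=float) + rng.normal(
        0, 4, (int(mask.sum()), 3)
    )
    return np.clip(img, 0, 255).astype(np.uint8)
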