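# Methods

## Scope and model

`phenotag` implements a validation pipeline for phenology derived from
opportunistic plant observations. Its components are: a 39-class
species–phenostage registry with label semantics; an SVM classifier over
image-derived feature vectors; vegetative exclusion and grouped 1.5 × IQR
outlier filtering; grid-cell median day-of-year (DOY) estimation;
interannual difference summaries; and simple Mantel tests between the
opportunistic and systematic sources. A synthetic-data module generates
all inputs, so every stage is testable without external downloads.

## The registry and label semantics

Nine woody species carry between 3 and 5 stages each (39 classes total).
Reproductive stages are ranked (seedling < flowering bud < flowering <
unripe fruit < fruit < ripe fruit < senescence); an image showing several
reproductive stages takes the *most advanced* one. `vegetative` is
unranked: it means "no reproductive organs visible" and is returned only
when nothing ranked is present. The undivided `fruit` label is fixed in
the registry for the three species whose unripe/ripe distinction is not
reliably visible in the field (*Acer platanoides*, *Betula pendula*,
*Fagus sylvatica*); `seedling` exists only for *Fagus sylvatica*. The
senescence-vs-ripe-fruit rank order is a registry convention — the
labeling rules never present that conflict directly, so senescence is
placed last as the seasonally latest stage.

A bundled CSV (`data/reference_class_metrics.csv`) carries the published
per-class train/test counts and precision/recall/F1 of the original
classifier; it is a fixed reference table for worked examples, not an
output of this package. Its per-row numbers imply an overall accuracy of
95.9% (≈ 96%) and 15 classes with F1 = 1.0.

## Classifier

Feature vectors default to 1792 dimensions, the length of the deep
features produced by the pre-trained CNN the workflow assumes. The
decision function is a linear-kernel SVM (C = 1) with one-vs-one voting —
deterministic and strong on high-dimensional transfer features; the
kernel, regularization and class weighting of the original model are not
published, so these defaults are declared, not inferred. Features are not
scaled by default (the synthetic stand-ins share a common scale);
`scale=True` standardizes first.

The stratified 80/20 split gives each class `floor(0.8·n_c)` training
records (clamped to [1, n_c − 1]); remaining slots up to
`round(0.8·N)` are distributed one per class in a seeded random order.
Evaluation derives every metric from the confusion matrix alone; a class
never predicted has precision 0 by convention (documented, avoids 0/0).

The CNN is represented by a `FeatureExtractor` protocol. Shipped
implementations: an identity pass-through for precomputed vectors, and a
deliberately simple toy extractor (8-bin per-channel color histograms
plus channel means/s.d.) paired with a toy specimen renderer, so the
image → feature → class path is exercised end to end in tests.

## Outlier filtering

Within each (species, stage, year) group, quartiles are computed by
linear interpolation between order statistics (the common default of
mainstream numeric stacks; the original convention is unstated) and
records strictly beyond [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are removed —
"beyond" is strict, so values exactly at a bound are kept. The filter is
single-pass: re-filtering the kept records could remove more, and that is
deliberately not done. Groups smaller than 4 pass through unfiltered,
since quartiles on so few records are unstable. Removed records are
written with their group bounds for audit.

## Grid aggregation

The native coordinate system is an abstract planar km grid (the real
tessellation and projection of any particular country are not
reproduced). Cells are half-open: cell index = floor((coord − origin) /
size), so every in-extent point maps to exactly one cell. The cell
estimate is the median DOY of the group; a singleton group contributes
its own DOY; an even group takes the midpoint of the central pair.

## Comparison

Systematic networks record a stage's *onset* (first individual showing
the stage); opportunistic data are summarized by the *median observation
date*, which always lags the onset. The pipeline therefore compares only
lag-invariant structure, restricted to the stages a systematic network
reports (flowering, ripe fruit, senescence):

* **Interannual differences** — per cell, DOY(year b) − DOY(year a) for
  consecutive years, computed within each source over that source's cells
  with estimates in all configured years; summarized by median and
  quartiles.
* **Simple Mantel test** — Euclidean distance matrices of the two
  sources' cell DOYs over the cells shared in a given year; r_M is the
  Pearson correlation of the strictly-upper triangles. Significance is a
  one-tailed permutation test (large positive r_M extreme — the analysis
  asks for positive spatial correspondence), built by jointly permuting
  rows and columns of one matrix; p = (1 + #{r_perm ≥ r_obs}) / (1 + N)
  with the observed statistic included in numerator and denominator (the
  standard unbiased estimator), so p ≥ 1/(N + 1). Default N = 9,999; the
  pipeline demo uses 999 to keep runs short. Zero variance in either
  triangle yields an explicitly flagged undefined result (r_M = NaN)
  rather than a silent number. Ties in the permutation distribution are
  counted with a 1e-12 tolerance so exact enumeration (available for
  n ≤ 8) and sampling agree.

No multiple-testing correction is applied across species or years, and no
partial (spatial-distance-conditioned) Mantel variant is provided; the
analysis is a set of independent pairwise tests by design.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any real dataset:

* **Feature clusters.** One isotropic Gaussian per class; centroid
  coordinates ~ N(0, 6²), within-class spread 1 (separation/spread = 6).
  Class sizes default to the reference table's train+test counts
  (~20–130 per class, 2,888 total). In 1792 dimensions this ratio puts a
  linear SVM in the near-perfect regime by construction; held-out
  accuracy ≥ 0.95 is a property of that regime, not a reproduction of the
  original model's 96%.
* **Latent field.** True mean DOY per (species, stage, year, cell) =
  stage baseline + species offset (4 d per species index) + year effect +
  linear gradient + site effect. Stage baselines (DOY 95–285) follow the
  seasonal order and are validated against it. The gradient (default
  0.3 d/km along y, a latitude/elevation proxy) and the year effects
  (default 0/+10/+2 d for 2020–2022, reproducing a late 2021 and an
  early-ish 2022) are shared between both data sources — that shared
  structure is what the Mantel test is meant to detect. The site effect
  (s.d. 2 d) is drawn once per (species, year, cell) and shared across
  stages, so stage order holds in every cell by construction rather than
  with high probability.
* **Observations.** Per cell, class and year, counts are Poisson with
  rate intensity × bias(cell); the bias map is the population-density
  multiplier (uniform by default; its real-world magnitude is not
  parameterized anywhere, so it is a free knob). DOY = cell truth +
  N(0, 3 d), rounded and clipped to the calendar (Feb 29 allowed in leap
  years). Vegetative records (default fraction 0.5, within the
  real-world 40–75% range) are uniform over DOY 60–330. Planted outliers
  are displaced from their group median by 5·IQR + 10 d toward the side
  with calendar room, guaranteeing they lie beyond 4×IQR — the regime the
  filter must catch.
* **Onsets.** One record per site × species × stage × year at cell
  centers by default; onset = cell truth − onset lead (default 7 d) +
  N(0, 2 d). With symmetric noise the opportunistic cell median exceeds
  the systematic onset by the lead in expectation, which the pipeline
  recovers.

What the simulation does *not* model: weekday/holiday and road-proximity
observation bias, species misidentification by the app, heavy-tailed or
skewed DOY noise, spatially correlated site effects, and real geography.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and its statistical calibration under the stated assumptions —
not that any particular real data stream satisfies those assumptions.

## Problem sizes and numerical choices

The demo pipeline and the acceptance script use 64-dimensional features
for the observation-annotation path (the class structure, not the
dimensionality, is what that path exercises); classifier-regime checks
use the full 1792 dimensions. The default domain is 100 × 100 km at
10 km cells (100 cells), intensity 2 records/cell/class/year
(≈ 200 records per class-year). Mantel checks in tests use 999
permutations with fixed seeds; the library default remains 9,999.
Parameter-recovery tolerances (±2 d on a +10 d year effect and a 7 d
onset lead) follow from sampling error at those sizes. All generators and
the pipeline are pure functions of (config, seed); outputs embed the seed
and a config hash, and reruns are byte-identical.

## Known limitations

* The Mantel test's permutation null assumes exchangeable cells; spatial
  autocorrelation in real cell values can inflate significance. The
  synthetic site effects are independent across cells, so the type-I
  calibration shown here does not transfer to strongly autocorrelated
  fields.
* The IQR filter assumes a unimodal DOY distribution per group; for
  stages with genuinely bimodal seasons it would trim real signal.
* `run_comparison` treats combinations with fewer than 3 shared cells as
  absent (reported with NaN statistics) rather than estimating anything.
* The toy image extractor is illustrative; it is not a stand-in of the
  deep features' quality, only of the interface.
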