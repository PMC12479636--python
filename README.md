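# phenotag

Automated phenological-stage (phenostage) annotation of opportunistic
plant observations, and validation of the derived phenology against
systematic records.

## The problem

Plant identification apps produce huge numbers of opportunistic records —
an image, a location, a date — but no phenological label. Systematic
phenology networks (trained volunteers following a protocol) produce
sparse but standardized *onset* dates. `phenotag` implements, as a tested
pipeline, a workflow that bridges the two:

1. **Classify.** Each image is represented by a fixed-length deep-feature
   vector from a pre-trained CNN; a multi-class SVM is trained on labeled
   vectors to separate all 39 species–phenostage combinations of 9 woody
   species (stages: seedling, flowering bud, flowering, unripe/ripe or
   undivided fruit, senescence, vegetative). Images with several stages
   visible are labeled with the *most advanced* stage.
2. **Annotate and filter.** The classifier labels every opportunistic
   record; vegetative records are excluded; temporal outliers are removed
   per species–stage–year group by the 1.5 × IQR rule
   (drop if DOY ∉ [Q1 − 1.5·IQR, Q3 + 1.5·IQR], strict).
3. **Aggregate.** Records are binned on a 10 × 10 km planar grid; each
   (cell, species, stage, year) gets the median day of year (DOY); a cell
   with a single record uses that record's DOY.
4. **Compare.** Because a systematic *onset* always precedes the
   opportunistic *median date*, levels are not compared directly. Instead
   the pipeline compares lag-invariant structure: per-cell interannual DOY
   differences between consecutive years, and simple Mantel tests —
   the Pearson correlation r_M between the Euclidean distance matrices of
   the two sources' cell DOYs over shared cells, with a one-tailed
   permutation test (9,999 permutations by default,
   p = (1 + #{r_perm ≥ r_obs}) / (1 + N)).

The CNN itself is out of scope; it is abstracted behind a
`FeatureExtractor` interface, and a synthetic-data module generates every
input the pipeline needs: per-class Gaussian feature clusters, a latent
spatiotemporal phenology field (stage order, year effects, a spatial
gradient, site effects), population-density observation bias, planted
outliers, and systematic onsets that lead the opportunistic median by a
configurable number of days.

## Worked example

```python
import phenotag as pt

cfg = pt.PipelineConfig(out_dir="demo_run", seed=1)
artifacts = pt.run_all(cfg)
```

This simulates labeled features and observations, trains and evaluates
the 39-class classifier, annotates, filters, grids and compares. On the
demo configuration (64-d features, 100 × 100 km domain, years 2020–2022
with year effects 0/+10/+2 days, onset lead 7 days) it prints via the
artifacts:

```
evaluation_report.json : accuracy 1.0          # synthetic clusters are separable
comparison.csv         : 57 Mantel rows, all flowering rows p < 0.05
comparison.json        : median interannual difference +10 d (2020→2021)
                         and −8 d (2021→2022) in both sources
```

i.e. the configured year effects are recovered identically from the
opportunistic and the systematic side, and the shared spatial gradient
makes the Mantel correlations significant — the behaviour the method is
designed to detect. The same chain is available stage by stage from the
shell:

```bash
phenotag simulate -o run/ --seed 1
phenotag train    -o run/ --seed 1
phenotag evaluate -o run/
phenotag annotate -o run/
phenotag filter   -o run/
phenotag grid     -o run/
phenotag compare  -o run/ --n-perm 999
```

A bundled reference table
(`phenotag.load_reference_metrics()`) carries the published per-class
precision/recall/F1 and image counts of the original 39-class classifier
and backs the worked-example tests (e.g. overall accuracy ≈ 96%, 15
classes with F1 = 1.0).

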