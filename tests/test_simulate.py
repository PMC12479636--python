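"""Generators: feature clusters, latent phenology field, observations, onsets."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist, pdist

import phenotag as pt
from phenotag.scheme import STAGE_RANK, Stage


TWO_CLASSES = {
    ("Rosa canina", Stage.FLOWERING): 5,
    ("Rosa canina", Stage.RIPE_FRUIT): 5,
}


class TestFeatureClusters:
    def test_two_well_separated_clusters(self, scheme):
        cfg = pt.FeatureSimConfig(dim=8, centroid_scale=20.0, spread=0.5,
                                  class_sizes=TWO_CLASSES, seed=0)
        data = pt.generate_feature_dataset(cfg, scheme)
        assert len(data) == 10
        a = data.X[data.stage == "flowering"]
        b = data.X[data.stage == "ripe_fruit"]
        within = max(pdist(a).max(), pdist(b).max())
        between = cdist(a, b).min()
        assert within < between

    def test_zero_spread_collapses_to_centroids(self, scheme):
        cfg = pt.FeatureSimConfig(dim=4, spread=0.0, class_sizes=TWO_CLASSES, seed=1)
        data = pt.generate_feature_dataset(cfg, scheme)
        for st in ("flowering", "ripe_fruit"):
            X = data.X[data.stage == st]
            assert np.all(X == X[0])

    def test_same_seed_bit_identical(self, scheme, small_feat_cfg):
        a = pt.generate_feature_dataset(small_feat_cfg, scheme)
        b = pt.generate_feature_dataset(small_feat_cfg, scheme)
        assert np.array_equal(a.X, b.X)
        assert list(a.ids) == list(b.ids)

    def test_class_sizes_exact(self, tiny_feature_set, scheme):
        counts = pd.Series(tiny_feature_set.labels).value_counts()
        assert (counts == 12).all() and len(counts) == 39

    def test_unknown_class_rejected(self, scheme):
        cfg = pt.FeatureSimConfig(
            dim=4, class_sizes={("Rosa canina", Stage.SEEDLING): 3}, seed=0
        )
        with pytest.raises(ValueError, match="not in scheme"):
            pt.generate_feature_dataset(cfg, scheme)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            pt.FeatureSimConfig(dim=1)
        with pytest.raises(ValueError):
            pt.FeatureSimConfig(spread=-1.0)


class TestPhenologyField:
    def test_stage_order_preserved_in_every_cell_and_year(self, small_field, scheme):
        for sp in scheme.species:
            ranked = [s for s in scheme.stages_for(sp) if s in STAGE_RANK]
            ranked.sort(key=STAGE_RANK.get)
            for year in small_field.years:
                grids = [small_field.mean_grid(sp, s, year) for s in ranked]
                for g1, g2 in zip(grids, grids[1:]):
                    assert np.all(g1 < g2)

    def test_misordered_baselines_rejected(self):
        with pytest.raises(ValueError, match="order"):
            pt.PhenologyFieldConfig(
                stage_baselines={Stage.FLOWERING: 200.0, Stage.RIPE_FRUIT: 150.0}
            )

    def test_gradient_shifts_doy_along_axis(self, small_field):
        g = small_field.mean_grid("Rosa canina", Stage.FLOWERING, 2020)
        col_means = g.mean(axis=0)  # along y
        slope = np.polyfit((np.arange(len(col_means)) + 0.5) * 10, col_means, 1)[0]
        assert slope == pytest.approx(0.3, abs=0.1)


class TestOpportunisticSampling:
    def test_year_effect_recovered_from_sample_means(self, scheme):
        cfg = pt.PhenologyFieldConfig(
            years=(2020, 2021), year_effects={2020: 0.0, 2021: 10.0},
            gradient_days_per_km=0.0, seed=5,
        )
        field = pt.PhenologyField(cfg, scheme)
        obs = pt.sample_opportunistic_observations(
            field, intensity=2.0, vegetative_fraction=0.0, seed=7,
            species=["Rosa canina"], stages=[Stage.FLOWERING],
        )
        means = obs.records.groupby("year")["doy"].mean()
        assert len(obs.records) > 300
        assert means[2021] - means[2020] == pytest.approx(10.0, abs=2.0)

    def test_population_bias_scales_counts(self, small_field):
        bias = np.ones((10, 10))
        bias[0, 0] = 5.0
        obs = pt.sample_opportunistic_observations(
            small_field, intensity=20.0, bias=bias, vegetative_fraction=0.0,
            seed=2, species=["Rosa canina"], stages=[Stage.FLOWERING],
        )
        df = obs.records
        cell = (df.x // 10).astype(int) * 100 + (df.y // 10).astype(int)
        counts = cell.value_counts()
        ref = counts[counts.index != 0].mean()
        assert counts[0] / ref == pytest.approx(5.0, rel=0.25)

    def test_no_planted_outliers_at_zero_rate(self, small_field):
        obs = pt.sample_opportunistic_observations(
            small_field, intensity=2.0, outlier_rate=0.0,
            vegetative_fraction=0.0, seed=3,
        )
        assert not obs.records["is_outlier"].any()
        # noise tails beyond the group 1.5*IQR bounds stay rare
        frac_beyond = []
        for _, grp in obs.records.groupby(["species", "stage_true", "year"]):
            b = pt.iqr_bounds(grp["doy"])
            frac_beyond.append(b.is_outlier(grp["doy"].to_numpy()).mean())
        assert np.mean(frac_beyond) < 0.03

    def test_planted_outliers_displaced_beyond_4_iqr(self, small_field):
        obs = pt.sample_opportunistic_observations(
            small_field, intensity=2.0, outlier_rate=0.05,
            vegetative_fraction=0.0, seed=4,
        )
        df = obs.records
        assert df["is_outlier"].sum() > 0
        for _, grp in df.groupby(["species", "stage_true", "year"]):
            clean = grp[~grp["is_outlier"]]["doy"].to_numpy()
            q1, q3 = np.percentile(clean, [25, 75])
            iqr = q3 - q1
            for d in grp[grp["is_outlier"]]["doy"]:
                assert d < q1 - 4 * iqr or d > q3 + 4 * iqr

    def test_vegetative_fraction_and_feature_sidecar(self, small_field, small_feat_cfg):
        obs = pt.sample_opportunistic_observations(
            small_field, feat_cfg=small_feat_cfg, intensity=1.0,
            vegetative_fraction=0.5, seed=6,
        )
        frac = (obs.records["stage_true"] == "vegetative").mean()
        assert frac == pytest.approx(0.5, abs=0.02)
        assert obs.features is not None
        assert obs.features.shape == (len(obs.records), 16)

    def test_determinism(self, small_field):
        a = pt.sample_opportunistic_observations(small_field, intensity=1.0, seed=9)
        b = pt.sample_opportunistic_observations(small_field, intensity=1.0, seed=9)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_doy_consistent_with_date_and_domain(self, small_field):
        obs = pt.sample_opportunistic_observations(small_field, intensity=1.0, seed=10)
        df = obs.records
        derived = pd.to_datetime(df["date"]).dt.dayofyear
        assert (derived == df["doy"]).all()
        assert df["x"].between(0, 100).all() and df["y"].between(0, 100).all()


class TestSystematicOnsets:
    def test_noiseless_onset_is_truth_minus_lead(self, scheme):
        cfg = pt.PhenologyFieldConfig(onset_lead_days=7.0, seed=8)
        field = pt.PhenologyField(cfg, scheme)
        onsets = pt.sample_systematic_onsets(
            field, noise_sd=0.0, seed=0,
            species=["Rosa canina"], stages=[Stage.RIPE_FRUIT],
        )
        for r in onsets.itertuples():
            i, j = field.cell_of(r.x, r.y)
            truth = field.cell_mean("Rosa canina", Stage.RIPE_FRUIT, r.year, i, j)
            assert r.doy == np.clip(np.rint(truth - 7.0), 1, 366)

    def test_one_record_per_site_species_stage_year(self, small_field):
        onsets = pt.sample_systematic_onsets(small_field, seed=1)
        dup = onsets.duplicated(["site_id", "species", "stage", "year"])
        assert not dup.any()
        # only stages a systematic network reports
        assert set(onsets["stage"]) <= {"flowering", "ripe_fruit", "senescence"}

    def test_lag_property_onset_leads_opportunistic_median(self, small_field):
        sp, st = "Sambucus nigra", Stage.FLOWERING
        obs = pt.sample_opportunistic_observations(
            small_field, intensity=4.0, vegetative_fraction=0.0, seed=11,
            species=[sp], stages=[st],
        )
        onsets = pt.sample_systematic_onsets(
            small_field, seed=11, species=[sp], stages=[st]
        )
        df = obs.records.copy()
        df["cell"] = list(zip((df.x // 10).astype(int), (df.y // 10).astype(int)))
        med = df.groupby(["cell", "year"])["doy"].median()
        ons = onsets.set_index(
            [onsets.x.floordiv(10).astype(int).combine(
                onsets.y.floordiv(10).astype(int), lambda a, b: (a, b)), "year"]
        )["doy"]
        joined = pd.concat([med, ons], axis=1, keys=["opp", "sys"]).dropna()
        lag = (joined["opp"] - joined["sys"]).mean()
        assert lag == pytest.approx(7.0, abs=1.0)

    def test_determinism(self, small_field):
        a = pt.sample_systematic_onsets(small_field, seed=2)
        b = pt.sample_systematic_onsets(small_field, seed=2)
        pd.testing.assert_frame_equal(a, b)
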