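"""Stratified splitting, SVM training, prediction and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support

import phenotag as pt
from phenotag.classify import ToyImageExtractor, class_label
from phenotag.scheme import Stage
from phenotag.simulate import render_toy_specimen


def _two_class_set(n_a=10, n_b=10, dim=4, gap=20.0, seed=0):
    rng = np.random.default_rng(seed)
    Xa = rng.normal(0, 1, (n_a, dim))
    Xb = rng.normal(gap, 1, (n_b, dim))
    return pt.LabeledFeatureSet(
        ids=np.arange(n_a + n_b),
        X=np.vstack([Xa, Xb]),
        species=np.array(["Rosa canina"] * (n_a + n_b), dtype=object),
        stage=np.array(["flowering"] * n_a + ["ripe_fruit"] * n_b, dtype=object),
    )


class TestStratifiedSplit:
    def test_exact_proportion_class_of_10(self):
        data = _two_class_set(10, 10)
        tr, te = pt.stratified_split(data, 0.8, seed=1)
        for stage in ("flowering", "ripe_fruit"):
            assert (tr.stage == stage).sum() == 8
            assert (te.stage == stage).sum() == 2

    def test_rounding_rule_class_of_99(self):
        data = _two_class_set(99, 10)
        tr, te = pt.stratified_split(data, 0.8, seed=1)
        assert (tr.stage == "flowering").sum() in (79, 80)
        assert len(tr) + len(te) == 109

    def test_partition_disjoint_and_exhaustive(self, tiny_feature_set):
        tr, te = pt.stratified_split(tiny_feature_set, 0.8, seed=2)
        ids = set(tr.ids) | set(te.ids)
        assert len(ids) == len(tiny_feature_set)
        assert not set(tr.ids) & set(te.ids)
        # global fraction within one record per class of the target
        assert len(tr) == pytest.approx(0.8 * len(tiny_feature_set), abs=39)

    def test_determinism(self, tiny_feature_set):
        a = pt.stratified_split(tiny_feature_set, 0.8, seed=3)
        b = pt.stratified_split(tiny_feature_set, 0.8, seed=3)
        assert np.array_equal(a[0].ids, b[0].ids)
        assert np.array_equal(a[1].ids, b[1].ids)

    def test_singleton_class_error_names_class(self):
        data = _two_class_set(1, 10)
        with pytest.raises(ValueError, match="flowering"):
            pt.stratified_split(data, 0.8, seed=0)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            pt.stratified_split(_two_class_set(), 1.0)


class TestTrainPredict:
    def test_separable_classes_perfect_training_accuracy(self):
        data = _two_class_set(gap=20.0)
        clf = pt.train_classifier(data)
        assert (pt.predict(clf, data.X) == data.labels).all()

    def test_single_class_rejected(self):
        data = _two_class_set(10, 0)
        with pytest.raises(ValueError, match="2 classes"):
            pt.train_classifier(data)

    def test_dimension_mismatch_rejected(self):
        clf = pt.train_classifier(_two_class_set(dim=4))
        with pytest.raises(ValueError, match="dimension"):
            pt.predict(clf, np.zeros((3, 5)))

    def test_empty_input_empty_output(self):
        clf = pt.train_classifier(_two_class_set(dim=4))
        assert len(pt.predict(clf, np.empty((0, 4)))) == 0

    def test_centroid_predicts_own_class(self, tiny_feature_set, scheme, small_feat_cfg):
        from phenotag.simulate import ClassClusterModel

        tr, _ = pt.stratified_split(tiny_feature_set, 0.8, seed=0)
        clf = pt.train_classifier(tr)
        clusters = ClassClusterModel(scheme, small_feat_cfg)
        for cls in [("Rosa canina", Stage.FLOWERING), ("Fagus sylvatica", Stage.SEEDLING)]:
            pred = pt.predict(clf, clusters.centroids[cls][None, :])[0]
            assert pred == class_label(*cls)

    def test_deterministic_predictions(self, tiny_feature_set):
        tr, te = pt.stratified_split(tiny_feature_set, 0.8, seed=0)
        clf = pt.train_classifier(tr)
        assert np.array_equal(pt.predict(clf, te.X), pt.predict(clf, te.X))


class TestEvaluate:
    def test_perfect_predictions(self):
        data = _two_class_set(gap=20.0)
        clf = pt.train_classifier(data)
        rep = pt.evaluate(clf, data)
        assert rep.accuracy == 1.0
        assert (rep.per_class["f1"] == 1.0).all()

    def test_confusion_matrix_invariants(self, tiny_feature_set):
        tr, te = pt.stratified_split(tiny_feature_set, 0.8, seed=0)
        clf = pt.train_classifier(tr)
        rep = pt.evaluate(clf, te)
        assert rep.confusion.sum() == len(te)
        assert (rep.confusion >= 0).all()
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / len(te))

    def test_degenerate_single_predicted_class(self):
        """All predictions one class on a balanced 2-class test set."""
        data = _two_class_set(6, 6, gap=20.0)
        clf = pt.train_classifier(data)
        shifted = pt.LabeledFeatureSet(
            ids=data.ids, X=np.full_like(data.X, -10.0),
            species=data.species, stage=data.stage,
        )
        rep = pt.evaluate(clf, shifted)
        assert rep.accuracy == 0.5
        pc = rep.per_class
        winner = pc[pc["recall"] == 1.0]
        loser = pc[pc["recall"] == 0.0]
        assert len(winner) == 1 and len(loser) == 1
        assert loser["precision"].iloc[0] == 0.0  # never predicted -> 0 by convention

    def test_metrics_match_independent_sklearn_computation(self, tiny_feature_set):
        tr, te = pt.stratified_split(tiny_feature_set, 0.8, seed=0)
        clf = pt.train_classifier(tr)
        rep = pt.evaluate(clf, te)
        y_true = te.labels.astype(str)
        y_pred = pt.predict(clf, te.X).astype(str)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=rep.labels, zero_division=0
        )
        assert np.allclose(rep.per_class["precision"], p)
        assert np.allclose(rep.per_class["recall"], r)
        assert np.allclose(rep.per_class["f1"], f)

    def test_accuracy_invariant_under_relabeling(self, tiny_feature_set):
        tr, te = pt.stratified_split(tiny_feature_set, 0.8, seed=0)
        clf = pt.train_classifier(tr)
        rep = pt.evaluate(clf, te)
        # a consistent permutation of class names cannot change the trace
        perm = np.random.default_rng(0).permutation(len(rep.labels))
        cm = rep.confusion[np.ix_(perm, perm)]
        assert np.trace(cm) == np.trace(rep.confusion)

    def test_accuracy_approaches_one_as_spread_vanishes(self, scheme):
        sizes = {cls: 8 for cls in scheme.classes}
        accs = []
        for spread in (3.0, 0.1):
            cfg = pt.FeatureSimConfig(dim=8, centroid_scale=3.0, spread=spread,
                                      class_sizes=sizes, seed=5)
            data = pt.generate_feature_dataset(cfg, scheme)
            tr, te = pt.stratified_split(data, 0.8, seed=5)
            accs.append(pt.evaluate(pt.train_classifier(tr), te).accuracy)
        assert accs[1] > accs[0] or accs[0] == 1.0
        assert accs[1] == 1.0


class TestF1:
    @pytest.mark.parametrize(
        "p, r, expected",
        [(0.77, 0.87, 0.82), (1.0, 1.0, 1.0), (1.0, 0.71, 0.83), (0.0, 0.0, 0.0)],
    )
    def test_examples(self, p, r, expected):
        assert round(pt.f1_score(p, r), 2) == expected

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bounded_by_min_and_symmetric(self, p, r):
        f = pt.f1_score(p, r)
        assert 0 <= f <= max(p, r) + 1e-12
        assert f == pytest.approx(pt.f1_score(r, p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pt.f1_score(1.2, 0.5)


class TestToyImagePath:
    def test_image_to_feature_to_class_end_to_end(self, rng):
        """Rendered toy specimens are separable by the toy extractor."""
        classes = [("Rosa canina", Stage.FLOWERING, 0),
                   ("Rosa canina", Stage.RIPE_FRUIT, 0),
                   ("Fagus sylvatica", Stage.SENESCENCE, 5)]
        images, species, stage = [], [], []
        for sp, st_, idx in classes:
            for _ in range(12):
                images.append(render_toy_specimen(st_, idx, rng))
                species.append(sp)
                stage.append(st_.value)
        X = ToyImageExtractor().extract(images)
        data = pt.LabeledFeatureSet(
            ids=np.arange(len(X)), X=X,
            species=np.array(species, dtype=object),
            stage=np.array(stage, dtype=object),
        )
        tr, te = pt.stratified_split(data, 0.75, seed=0)
        rep = pt.evaluate(pt.train_classifier(tr, scale=True), te)
        assert rep.accuracy >= 0.8
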