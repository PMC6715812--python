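import numpy as np
import pandas as pd
import pytest

import glcmrad as gr
from glcmrad.classify import ConfusionMatrix, forest_vote_scores
from glcmrad.imaging import ValidationError

from _oracles import auc_pair_counting


def _blobs(n_per_class=20, n_features=6, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(3 * n_per_class, n_features))
    y = np.repeat(["a", "b", "c"], n_per_class)
    X[:, 0] += np.repeat([0.0, sep, 2 * sep], n_per_class)
    return pd.DataFrame(X), y


class TestConfusionMetrics:
    def test_hand_computed_example(self):
        # embed TP=8, TN=20, FP=3, FN=2 for class "a" in a 2-class matrix
        cm = ConfusionMatrix(np.array([[8, 2], [3, 20]]), ("a", "b"))
        m = gr.confusion_metrics(cm, "a")
        assert m["accuracy"] == pytest.approx(28 / 33)
        assert m["specificity"] == pytest.approx(20 / 23)
        assert m["sensitivity"] == pytest.approx(0.800)
        assert m["f_score"] == pytest.approx(16 / 21)

    def test_perfect_classifier_scores_one(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), ("a", "b", "c"))
        for cls in ("a", "b", "c"):
            assert all(v == 1.0 for v in gr.confusion_metrics(cm, cls).values())

    def test_no_true_positives(self):
        cm = ConfusionMatrix(np.array([[0, 4], [0, 6]]), ("a", "b"))
        assert gr.confusion_metrics(cm, "a")["sensitivity"] == 0.0

    def test_counts_partition_total(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, size=(3, 3))
        cm = ConfusionMatrix(counts, ("a", "b", "c"))
        for cls in cm.classes:
            c = cm.one_vs_rest(cls)
            assert c["TP"] + c["TN"] + c["FP"] + c["FN"] == cm.total

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), int), ("a", "b"))
        with pytest.raises(ValidationError):
            gr.confusion_metrics(cm, "a")


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        y = ["a"] * 5 + ["b"] * 5
        scores = np.arange(10, 0, -1, dtype=float)
        auc, _ = gr.roc_auc(scores, y, "a", classes=["a", "b"])
        assert auc == 1.0

    def test_all_tied_scores_give_half(self):
        y = ["a"] * 4 + ["b"] * 6
        auc, _ = gr.roc_auc(np.ones(10), y, "a", classes=["a", "b"])
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_estimator(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.choice(["a", "b"], size=30)
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        scores = rng.integers(0, 6, size=30).astype(float)  # heavy ties
        auc, _ = gr.roc_auc(scores, y, "a", classes=["a", "b"])
        ref = auc_pair_counting(scores, y == "a")
        assert auc == pytest.approx(ref, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            gr.roc_auc(np.ones(4), ["a"] * 4, "a", classes=["a"])


class TestTrainers:
    def test_tree_separates_trivial_classes(self):
        X = pd.DataFrame({"f": [0.0, 0.1, 0.2, 5.0, 5.1, 5.2]})
        y = ["lo"] * 3 + ["hi"] * 3
        model = gr.train_decision_tree(X, y, seed=0)
        assert (model.predict(X.to_numpy()) == y).all()

    def test_single_class_input_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            gr.train_decision_tree(X, ["a", "a"])
        with pytest.raises(ValidationError):
            gr.train_random_forest(X, ["a", "a"])

    def test_forest_vote_fractions_sum_to_one_and_repeat(self):
        X, y = _blobs(10, seed=2)
        m1 = gr.train_random_forest(X, y, n_trees=50, seed=5)
        m2 = gr.train_random_forest(X, y, n_trees=50, seed=5)
        v1 = forest_vote_scores(m1, X.to_numpy())
        v2 = forest_vote_scores(m2, X.to_numpy())
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_allclose(v1.sum(axis=1), 1.0)

    def test_single_tree_forest_is_one_bootstrap_tree(self):
        X, y = _blobs(10, seed=3)
        m = gr.train_random_forest(X, y, n_trees=1, seed=0)
        assert len(m.estimators_) == 1

    def test_svm_standardization_makes_scale_irrelevant(self):
        X, y = _blobs(15, sep=3.0, seed=4)
        Xs = X.copy()
        Xs.iloc[:, 0] *= 1e6  # blow up the informative axis
        rep_raw = gr.crossvalidate("svm", X, y, k=5, seed=1, n_boot=100)
        rep_scaled = gr.crossvalidate("svm", Xs, y, k=5, seed=1, n_boot=100)
        assert abs(rep_raw.accuracy - rep_scaled.accuracy) < 0.15

    def test_svm_separates_gaussian_blobs(self):
        X, y = _blobs(15, sep=6.0, seed=6)
        rep = gr.crossvalidate("svm", X, y, k=5, seed=2, n_boot=100)
        assert rep.accuracy >= 0.95


class TestCrossvalidate:
    def test_perfectly_separable_classes_score_one(self):
        X, y = _blobs(10, sep=50.0, seed=7)
        rep = gr.crossvalidate("tree", X, y, k=5, seed=0, n_boot=100)
        assert rep.accuracy == 1.0
        assert (rep.per_class["accuracy"] == 1.0).all()

    def test_leave_one_out_predicts_every_scan_once(self):
        X, y = _blobs(4, sep=5.0, seed=8)
        rep = gr.crossvalidate("tree", X, y, k=len(y), seed=0, n_boot=100)
        assert rep.confusion.total == len(y)

    def test_too_many_folds_rejected(self):
        X, y = _blobs(2, seed=9)
        with pytest.raises(ValidationError):
            gr.crossvalidate("tree", X, y, k=50)

    def test_fixed_seed_reproduces_report(self):
        X, y = _blobs(8, sep=2.0, seed=10)
        a = gr.crossvalidate("forest", X, y, k=5, seed=4, n_boot=100,
                             n_trees=50)
        b = gr.crossvalidate("forest", X, y, k=5, seed=4, n_boot=100,
                             n_trees=50)
        pd.testing.assert_frame_equal(a.per_class, b.per_class)
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)

    def test_one_vs_rest_counts_partition_scans(self):
        X, y = _blobs(8, sep=1.0, seed=11)
        rep = gr.crossvalidate("tree", X, y, k=5, seed=0, n_boot=100)
        for cls in rep.classes:
            c = rep.confusion.one_vs_rest(cls)
            assert sum(c.values()) == rep.n_scans

    def test_permuted_labels_score_at_chance(self):
        """Shuffling labels must drive CV accuracy to the 1/3 chance level
        for every model family."""
        X, y = _blobs(15, sep=5.0, seed=12)
        rng = np.random.default_rng(13)
        y_perm = rng.permutation(y)
        n = len(y_perm)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for family in ("tree", "forest", "svm"):
            rep = gr.crossvalidate(family, X, y_perm, k=5, seed=3, n_boot=100,
                                   **({"n_trees": 100} if family == "forest" else {}))
            assert abs(rep.accuracy - 1 / 3) < 3 * se, family

    def test_animal_level_partition_keeps_repeat_scans_together(self):
        X, y = _blobs(12, sep=6.0, seed=14)
        animals = np.repeat(np.arange(12), 3)  # 3 scans per animal
        rep = gr.crossvalidate("tree", X, y, k=4, seed=0, groups=animals,
                               n_boot=100)
        assert rep.confusion.total == len(y)


class TestFeatureImportance:
    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(90, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = np.repeat(["a", "b", "c"], 30)
        X["signal"] = rng.normal(size=90) * 0.1 + np.repeat([0, 4, 8], 30)
        model = gr.train_random_forest(X, y, n_trees=100, seed=0)
        imp = gr.feature_importance(model, X.columns)
        assert imp.index[0] == "signal"
        assert (imp >= 0).all()
        # pure-noise features pick up only residual bootstrap gain
        assert imp.drop("signal").max() < 0.2 * imp["signal"]

    def test_unused_feature_has_zero_importance(self):
        X = pd.DataFrame({"used": [0.0, 0, 0, 1, 1, 1], "constant": [2.0] * 6})
        y = ["a"] * 3 + ["b"] * 3
        model = gr.train_random_forest(X, y, n_trees=20, seed=1)
        imp = gr.feature_importance(model, X.columns)
        assert imp["constant"] == 0.0

    def test_untrained_model_rejected(self):
        from sklearn.ensemble import RandomForestClassifier

        with pytest.raises(ValidationError):
            gr.feature_importance(RandomForestClassifier(), ["a"])


class TestConfidenceInterval:
    def test_constant_metric_zero_width(self):
        from glcmrad.classify import confidence_interval

        lo, hi = confidence_interval(lambda idx: 0.7, 50, seed=0, n_boot=200)
        assert lo == hi == pytest.approx(0.7)

    def test_interval_clipped_to_unit_range(self):
        from glcmrad.classify import confidence_interval

        rng = np.random.default_rng(0)
        vals = rng.normal(0.98, 0.2, size=2000)
        i = iter(vals)
        lo, hi = confidence_interval(lambda idx: next(i), 30, seed=0, n_boot=2000)
        assert 0.0 <= lo <= hi <= 1.0

    def test_deterministic_under_seed(self):
        from glcmrad.classify import confidence_interval

        def metric(idx):
            return float(np.mean(idx) / 100)

        a = confidence_interval(metric, 40, seed=7, n_boot=300)
        b = confidence_interval(metric, 40, seed=7, n_boot=300)
        assert a == b
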