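import numpy as np
import pytest
from scipy.stats import rankdata

from hrvbalance import (
    ClassifierSpec,
    confusion_matrix,
    feature_importance,
    metrics_from_confusion,
    rank_and_mean_rank,
    roc_auc_ovr,
    run_benchmark,
    train_classifier,
)
from hrvbalance.benchmark import MODEL_KINDS, mean_rank_from_ranks

from conftest import make_dataset


def mann_whitney_auc(y_pos, scores):
    """Rank-statistic AUC oracle: P(score_pos > score_neg) + ½P(tie)."""
    ranks = rankdata(scores)
    n_pos = int(y_pos.sum())
    n_neg = len(y_pos) - n_pos
    u = ranks[y_pos.astype(bool)].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        cm = confusion_matrix([1, 2, 3], [1, 2, 3], labels=(1, 2, 3))
        assert np.array_equal(cm, np.eye(3, dtype=int))

    def test_counting(self):
        cm = confusion_matrix([1, 1, 2], [1, 2, 2], labels=(1, 2))
        assert cm.tolist() == [[1, 1], [0, 1]]

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(1, 8, size=100)
        y_pred = rng.integers(1, 8, size=100)
        cm = confusion_matrix(y_true, y_pred, labels=tuple(range(1, 8)))
        assert cm.sum() == 100

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([1, 9], [1, 1], labels=(1, 2))


class TestMetrics:
    def test_perfect_matrix_gives_ones(self):
        m = metrics_from_confusion(np.diag([5, 3, 2]))
        assert (m.accuracy, m.macro_precision, m.macro_recall, m.macro_f1) == (1, 1, 1, 1)

    def test_hand_worked_two_class_case(self):
        """cm [[2,1],[0,3]]: accuracy 5/6, macro precision (1+0.75)/2,
        macro recall (2/3+1)/2, macro F1 (0.8 + 6/7)/2."""
        m = metrics_from_confusion(np.array([[2, 1], [0, 3]]))
        assert m.accuracy == pytest.approx(5 / 6)
        assert m.macro_precision == pytest.approx(0.875)
        assert m.macro_recall == pytest.approx(5 / 6)
        assert m.macro_f1 == pytest.approx((0.8 + 6 / 7) / 2)

    def test_macro_invariant_to_class_permutation(self):
        cm = np.array([[5, 2, 0], [1, 7, 1], [0, 3, 4]])
        perm = [2, 0, 1]
        cm_p = cm[np.ix_(perm, perm)]
        a, b = metrics_from_confusion(cm), metrics_from_confusion(cm_p)
        assert a.macro_precision == pytest.approx(b.macro_precision)
        assert a.macro_recall == pytest.approx(b.macro_recall)
        assert a.macro_f1 == pytest.approx(b.macro_f1)

    def test_zero_predicted_class_flagged(self):
        m = metrics_from_confusion(np.array([[2, 0], [1, 0]]), labels=(1, 2))
        assert m.zero_predicted_classes == (2,)
        assert m.per_class[2]["precision"] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            metrics_from_confusion(np.zeros((2, 2)))


class TestRocAuc:
    def test_perfect_and_reversed_separation(self):
        y = np.array([1, 1, 2, 2])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        res = roc_auc_ovr(y, scores, labels=(1, 2))
        assert res.per_class_auc == {1: 1.0, 2: 1.0}
        rev = roc_auc_ovr(y, scores[:, ::-1], labels=(1, 2))
        assert rev.per_class_auc == {1: 0.0, 2: 0.0}

    def test_matches_rank_statistic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(20, 500))
            y = rng.integers(1, 4, size=n)
            scores = rng.random((n, 3))
            scores /= scores.sum(axis=1, keepdims=True)
            res = roc_auc_ovr(y, scores, labels=(1, 2, 3))
            for j, lab in enumerate((1, 2, 3)):
                pos = (y == lab).astype(int)
                if pos.all() or not pos.any():
                    continue
                assert res.per_class_auc[lab] == pytest.approx(
                    mann_whitney_auc(pos, scores[:, j]), abs=1e-12
                )

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(8)
        y = rng.integers(1, 3, size=2000)
        scores = rng.random((2000, 2))
        res = roc_auc_ovr(y, scores, labels=(1, 2))
        for v in res.per_class_auc.values():
            assert v == pytest.approx(0.5, abs=0.03)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([1, 1, 2, 2])
        scores = np.random.default_rng(0).random((4, 3))
        with pytest.warns(UserWarning, match="undefined"):
            res = roc_auc_ovr(y, scores, labels=(1, 2, 3))
        assert set(res.per_class_auc) == {1, 2}


def separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 0.3, size=(n, 4))
    b = rng.normal(5, 0.3, size=(n, 4))
    return make_dataset(np.vstack([a, b]), np.array([1] * n + [2] * n))


class TestTrainClassifier:
    def test_knn_predicts_local_label(self):
        ds = separable_toy()
        fitted = train_classifier(ClassifierSpec("knn"), ds)
        pred = fitted.predict(np.array([[0.0, 0.0, 0.0, 0.0], [5.0, 5.0, 5.0, 5.0]]))
        assert pred.tolist() == [1, 2]

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_all_models_fit_separable_toy(self, kind):
        ds = separable_toy(seed=1)
        fitted = train_classifier(ClassifierSpec(kind, seed=0), ds)
        assert (fitted.predict(ds.features) == ds.labels).mean() == 1.0

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_seeded_refits_are_reproducible(self, kind):
        ds = separable_toy(seed=2)
        p1 = train_classifier(ClassifierSpec(kind, seed=3), ds).predict_scores(ds.features)
        p2 = train_classifier(ClassifierSpec(kind, seed=3), ds).predict_scores(ds.features)
        assert np.allclose(p1, p2, atol=1e-6)

    def test_degenerate_training_set_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(5, 2)),
                          np.ones(5, dtype=int))
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(ClassifierSpec("knn"), ds)


class TestFeatureImportance:
    def _toy_with_noise_feature(self, seed=0):
        rng = np.random.default_rng(seed)
        signal = np.concatenate([rng.normal(0, 0.3, 40), rng.normal(4, 0.3, 40)])
        noise = rng.normal(size=80)
        feats = np.column_stack([signal, noise])
        return make_dataset(feats, np.array([1] * 40 + [2] * 40),
                            feature_names=("signal", "noise"))

    def test_noise_feature_scores_near_zero_and_signal_ranks_first(self):
        ds = self._toy_with_noise_feature()
        fitted = train_classifier(ClassifierSpec("knn"), ds)
        scores = feature_importance(fitted, ds, seed=1)
        assert scores[0] > 0.2          # shuffling the label-determining feature hurts
        assert abs(scores[1]) < 0.05    # pure noise is inert up to Monte-Carlo error
        ranks, mean = rank_and_mean_rank({"knn": scores}, ds.feature_names)
        assert ranks["knn"]["signal"] == 1.0

    def test_same_seed_reproduces_scores(self):
        ds = self._toy_with_noise_feature(seed=2)
        fitted = train_classifier(ClassifierSpec("knn"), ds)
        s1 = feature_importance(fitted, ds, seed=5)
        s2 = feature_importance(fitted, ds, seed=5)
        assert np.array_equal(s1, s2)

    def test_impurity_only_for_forest(self):
        ds = self._toy_with_noise_feature(seed=3)
        rf = train_classifier(ClassifierSpec("rf", {"n_estimators": 20}, seed=0), ds)
        imp = feature_importance(rf, ds, method="impurity")
        assert imp.shape == (2,) and imp[0] > imp[1]
        knn = train_classifier(ClassifierSpec("knn"), ds)
        with pytest.raises(ValueError, match="random forest"):
            feature_importance(knn, ds, method="impurity")

    def test_unknown_method(self):
        ds = self._toy_with_noise_feature(seed=4)
        fitted = train_classifier(ClassifierSpec("knn"), ds)
        with pytest.raises(ValueError, match="method"):
            feature_importance(fitted, ds, method="shap")


class TestMeanRank:
    # per-model rank rows of the nine HRV features as printed by the
    # emulated study's importance table
    PRINTED_RANKS = {
        "svm": {"SDNN": 2, "HR": 1, "LF": 6, "rmSSD": 3, "HF": 9, "LF/HF": 7,
                 "VLF": 4, "PNN50": 5, "TSP": 8},
        "rf": {"SDNN": 1, "HR": 4, "LF": 3, "rmSSD": 7, "HF": 2, "LF/HF": 5,
                "VLF": 9, "PNN50": 6, "TSP": 8},
        "nn": {"SDNN": 1, "HR": 3, "LF": 4, "rmSSD": 6, "HF": 2, "LF/HF": 5,
                "VLF": 7, "PNN50": 8, "TSP": 9},
        "knn": {"SDNN": 2, "HR": 1, "LF": 4, "rmSSD": 3, "HF": 9, "LF/HF": 5,
                 "VLF": 6, "PNN50": 7, "TSP": 8},
    }

    def test_printed_rank_rows_aggregate_to_known_means(self):
        mean = mean_rank_from_ranks(self.PRINTED_RANKS)
        assert mean["SDNN"] == pytest.approx(1.5)
        assert mean["TSP"] == pytest.approx(8.25)
        assert mean["HR"] == pytest.approx(2.25)
        assert list(mean)[0] == "SDNN" and list(mean)[-1] == "TSP"

    def test_agreeing_models_mean_equals_common_rank(self):
        scores = {"a": np.array([3.0, 2.0, 1.0]), "b": np.array([30.0, 20.0, 10.0])}
        ranks, mean = rank_and_mean_rank(scores, ("x", "y", "z"))
        assert mean == {"x": 1.0, "y": 2.0, "z": 3.0}

    def test_ties_get_average_rank(self):
        ranks, mean = rank_and_mean_rank({"m": np.array([1.0, 1.0, 0.0])}, ("a", "b", "c"))
        assert ranks["m"] == {"a": 1.5, "b": 1.5, "c": 3.0}

    def test_feature_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature set"):
            rank_and_mean_rank({"a": {"x": 1.0}, "b": {"y": 1.0}})


class TestRunBenchmark:
    def test_report_structure_and_internal_consistency(self):
        train = separable_toy(n=30, seed=5)
        test = separable_toy(n=10, seed=6)
        specs = [
            ClassifierSpec("knn"),
            ClassifierSpec("rf", {"n_estimators": 25}, seed=1),
        ]
        report = run_benchmark(train, test, specs, importance_repeats=3)
        assert set(report.models) == {"knn", "rf"}
        for name, mr in report.models.items():
            assert mr.confusion.sum() == test.n_samples
            recomputed = metrics_from_confusion(mr.confusion, report.labels)
            assert recomputed.macro_f1 == pytest.approx(mr.metrics.macro_f1)
            assert 0.0 <= mr.roc.macro_auc <= 1.0
            model_ranks = sorted(report.ranks[name].values())
            assert model_ranks == sorted(
                rankdata(-mr.importance, method="average").tolist()
            )
        assert set(report.mean_rank) == set(train.feature_names)
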