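import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion

from eegmap import (
    ConfigurationError,
    HyperparamSpace,
    confusion,
    evaluate,
    macro_metrics,
    random_search,
)


def metrics_rounded(labels, predictions, classes=("A", "B")):
    return tuple(
        round(v, 2) for v in macro_metrics(confusion(labels, predictions, classes))
    )


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
        for cls in ("A", "B"):
            tp, fp, tn, fn = c[cls]
            assert fp == 0 and fn == 0

    def test_all_wrong_binary(self):
        c = confusion(["A", "B"], ["B", "A"], ["A", "B"])
        for cls in ("A", "B"):
            tp, fp, tn, fn = c[cls]
            assert tp == 0 and tn == 0

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["A", "B"], size=60)
        predictions = rng.choice(["A", "B"], size=60)
        c = confusion(labels, predictions, ["A", "B"])
        for cls in ("A", "B"):
            tp = sum(1 for y, p in zip(labels, predictions) if y == cls == p)
            fp = sum(1 for y, p in zip(labels, predictions) if y != cls and p == cls)
            fn = sum(1 for y, p in zip(labels, predictions) if y == cls and p != cls)
            tn = 60 - tp - fp - fn
            assert c[cls] == (tp, fp, tn, fn)

    def test_agrees_with_sklearn_confusion_matrix(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(["A", "B"], size=40)
        predictions = rng.choice(["A", "B"], size=40)
        m = sk_confusion(labels, predictions, labels=["A", "B"])
        c = confusion(labels, predictions, ["A", "B"])
        assert c["A"] == (m[0, 0], m[1, 0], m[1, 1], m[0, 1])

    def test_unknown_prediction_label_rejected(self):
        with pytest.raises(ConfigurationError, match="predictions"):
            confusion(["A"], ["C"], ["A", "B"])


class TestMacroMetrics:
    def test_constant_majority_predictor_closed_form(self):
        """18-sample test set, 11 majority: the constant predictor lands on
        61.11 / 30.56 / 50.00 / 37.93 exactly."""
        labels = ["A"] * 11 + ["B"] * 7
        acc, prec, rec, f1 = metrics_rounded(labels, ["A"] * 18)
        assert (acc, prec, rec, f1) == (61.11, 30.56, 50.00, 37.93)

    def test_constant_minority_predictor_closed_form(self):
        labels = ["A"] * 11 + ["B"] * 7
        acc, prec, rec, f1 = metrics_rounded(labels, ["B"] * 18)
        assert (acc, prec, rec, f1) == (38.89, 19.44, 50.00, 28.00)

    def test_perfect_predictions_all_100(self):
        labels = ["A", "B"] * 5
        assert metrics_rounded(labels, labels) == (100.0, 100.0, 100.0, 100.0)

    @pytest.mark.parametrize("n_a,n_b", [(11, 7), (5, 5), (1, 9), (12, 6)])
    def test_constant_predictor_macro_recall_is_50(self, n_a, n_b):
        labels = ["A"] * n_a + ["B"] * n_b
        _, _, rec, _ = macro_metrics(confusion(labels, ["A"] * (n_a + n_b), ["A", "B"]))
        assert rec == pytest.approx(50.0)

    def test_accuracy_invariant_to_label_renaming(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(["A", "B"], size=30)
        predictions = rng.choice(["A", "B"], size=30)
        a = macro_metrics(confusion(labels, predictions, ["A", "B"]))
        swap = {"A": "B", "B": "A"}
        b = macro_metrics(
            confusion([swap[y] for y in labels], [swap[p] for p in predictions], ["A", "B"])
        )
        assert a[0] == pytest.approx(b[0])

    def test_empty_test_set_rejected(self):
        with pytest.raises(ConfigurationError):
            confusion([], [], ["A", "B"])


def _toy_data(n=40, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    y = np.array(["A", "B"] * (n // 2))
    shift = np.where(y == "A", -3.0, 3.0) if separable else 0.0
    X = rng.normal(size=(n, 2)) + np.c_[shift, np.zeros(n)]
    return X, y


class TestRandomSearch:
    def test_nb_returns_single_empty_candidate(self):
        X, y = _toy_data()
        assert random_search(HyperparamSpace("nb"), X, y, seed=0) == {}

    def test_sampled_domains_respect_printed_grids(self):
        rng = np.random.default_rng(0)
        svm = HyperparamSpace("svm")
        knn = HyperparamSpace("knn")
        rf = HyperparamSpace("rf")
        mlp = HyperparamSpace("mlp")
        for _ in range(200):
            p = svm.sample(rng)
            assert p["kernel"] in ("linear", "poly", "rbf")
            e = np.log2(p["C"])
            assert e == int(e) and -5 <= e <= 15
            if p["kernel"] == "rbf":
                g = np.log2(p["gamma"])
                assert g == int(g) and -15 <= g <= 3
            if p["kernel"] == "poly":
                assert p["degree"] in (3, 5, 7, 9)
            k = knn.sample(rng)["k"]
            assert k in range(3, 16, 2)
            r = rf.sample(rng)
            assert r["criterion"] in ("gini", "entropy")
            assert 2 <= r["min_samples_split"] <= 6
            assert 1 <= r["min_samples_leaf"] <= 6
            assert r["n_estimators"] == 3000
            assert 2 <= mlp.sample(rng)["hidden"] <= 1000

    def test_seeded_repeat_identical_choice(self):
        X, y = _toy_data()
        a = random_search(HyperparamSpace("knn"), X, y, n_iter=5, inner_folds=5, seed=3)
        b = random_search(HyperparamSpace("knn"), X, y, n_iter=5, inner_folds=5, seed=3)
        assert a == b

    def test_too_few_samples_per_class_rejected(self):
        X, y = _toy_data(n=10)
        with pytest.raises(ConfigurationError, match="10-fold"):
            random_search(HyperparamSpace("knn"), X, y, inner_folds=10, seed=0)


class TestEvaluate:
    def test_separable_data_scores_100(self):
        X, y = _toy_data(n=60, separable=True)
        result = evaluate(X[:, :1], y, "knn", seed=0, n_iter=3)
        assert result.mean("accuracy") == pytest.approx(100.0)
        assert result.std("accuracy") == pytest.approx(0.0)

    def test_label_shuffle_hovers_near_chance(self):
        rng = np.random.default_rng(4)
        X, y = _toy_data(n=60, separable=True)
        shuffled = rng.permutation(y)
        result = evaluate(X, shuffled, "nb", seed=1, n_iter=1)
        sigma = max(result.std("accuracy"), 100 / np.sqrt(12 * 10))
        assert abs(result.mean("accuracy") - 50.0) <= 3 * sigma

    def test_result_bookkeeping(self):
        X, y = _toy_data(n=40)
        result = evaluate(X, y, "knn", n_splits=4, seed=2, n_iter=2, inner_folds=5)
        assert len(result.per_split["accuracy"]) == 4
        assert len(result.chosen_params) == 4
        assert all("k" in p for p in result.chosen_params)
        for metric, values in result.per_split.items():
            assert all(0 <= v <= 100 for v in values)
        d = result.to_dict()
        assert set(d["summary"]) == {"accuracy", "precision", "recall", "f1"}

    def test_seeded_reproducibility(self):
        X, y = _toy_data(n=40)
        a = evaluate(X, y, "rf", n_splits=2, seed=5, n_iter=2, inner_folds=4,
                     space=HyperparamSpace("rf", n_estimators=20))
        b = evaluate(X, y, "rf", n_splits=2, seed=5, n_iter=2, inner_folds=4,
                     space=HyperparamSpace("rf", n_estimators=20))
        assert a.per_split == b.per_split
        assert a.chosen_params == b.chosen_params

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ConfigurationError):
            evaluate(X, ["A"] * 10, "nb")

    def test_tiny_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ConfigurationError, match=">= 2"):
            evaluate(X, ["A", "A", "A", "A", "B"], "nb")
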