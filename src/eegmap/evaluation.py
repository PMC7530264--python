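"""Classifier families, random hyperparameter search, macro metrics.

The evaluation harness mirrors a common small-sample protocol: ten
stratified random 80/20 train/test splits; inside each training portion
a 20-iteration random search scored by 10-fold cross-validated accuracy
picks the hyperparameters; the refit model is scored on the held-out
portion with accuracy, precision, recall and F1 computed per class from
one-vs-rest confusion counts and macro-averaged (equal class weight),
reported in percent as mean +/- standard deviation over the splits.

Hyperparameter domains:

* kNN: k over the odd values 3..15;
* MLP: one hidden layer, neurons log-uniform over 2..1000;
* SVM: kernel in {linear, poly, rbf}; C = 2^e, e in -5..15; for rbf
  gamma = 2^e, e in -15..3; for poly degree over the odd values 3..9;
* RF: criterion in {gini, entropy}, min_samples_split 2..6,
  min_samples_leaf 1..6, n_estimators fixed (default 3000);
* Naive Bayes: no hyperparameters.

Zero-division convention: the precision/recall/F1 of a class with no
predicted (or no true) members is 0, which gives constant ("degenerate")
predictors exact closed-form macro metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .core import ConfigurationError

FAMILIES = ("nb", "knn", "mlp", "rf", "svm")

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class."""

    counts: dict[str, tuple[int, int, int, int]]  # class -> (tp, fp, tn, fn)

    def __getitem__(self, cls: str) -> tuple[int, int, int, int]:
        return self.counts[cls]

    @property
    def classes(self) -> list[str]:
        return list(self.counts)

    @property
    def n_samples(self) -> int:
        first = next(iter(self.counts.values()))
        return sum(first)


def confusion(
    labels: Sequence, predictions: Sequence, classes: Sequence | None = None
) -> ConfusionCounts:
    """One-vs-rest confusion counts for each class."""
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) != len(predictions):
        raise ConfigurationError(
            f"{len(labels)} labels but {len(predictions)} predictions"
        )
    if not labels:
        raise ConfigurationError("empty test set")
    if classes is None:
        classes = sorted(set(labels))
    classes = list(classes)
    unknown = set(labels) - set(classes)
    if unknown:
        raise ConfigurationError(f"labels outside the class set: {sorted(unknown)}")
    unknown = set(predictions) - set(classes)
    if unknown:
        raise ConfigurationError(f"predictions outside the class set: {sorted(unknown)}")
    counts = {}
    for cls in classes:
        tp = sum(1 for y, p in zip(labels, predictions) if y == cls and p == cls)
        fp = sum(1 for y, p in zip(labels, predictions) if y != cls and p == cls)
        fn = sum(1 for y, p in zip(labels, predictions) if y == cls and p != cls)
        tn = len(labels) - tp - fp - fn
        counts[cls] = (tp, fp, tn, fn)
    return ConfusionCounts(counts=counts)


def macro_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """Macro-averaged (accuracy, precision, recall, F1), in percent.

    Per class: accuracy (tp+tn)/n, precision tp/(tp+fp), recall
    tp/(tp+fn), F1 the harmonic mean of the two; any 0/0 is taken as 0.
    Each metric is then averaged over the classes with equal weight.
    """
    if not counts.counts:
        raise ConfigurationError("no classes")
    if counts.n_samples == 0:
        raise ConfigurationError("empty test set")
    accs, precs, recs, f1s = [], [], [], []
    for tp, fp, tn, fn in counts.counts.values():
        n = tp + fp + tn + fn
        accs.append((tp + tn) / n)
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    mean = lambda xs: 100.0 * float(np.mean(xs))
    return mean(accs), mean(precs), mean(recs), mean(f1s)


# ---------------------------------------------------------------------------
# Hyperparameter spaces and random search


@dataclass
class HyperparamSpace:
    """A named classifier family plus its sampleable parameter domains."""

    family: str
    n_estimators: int = 3000  # RF only; the forest size is not searched
    mlp_max_iter: int = 400
    svm_max_iter: int = 200_000

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )

    def sample(self, rng: np.random.Generator) -> dict:
        """Draw one parameter set uniformly from the printed domains."""
        if self.family == "nb":
            return {}
        if self.family == "knn":
            return {"k": int(rng.choice(np.arange(3, 16, 2)))}
        if self.family == "mlp":
            # log-uniform over 2..1000
            h = int(round(np.exp(rng.uniform(np.log(2), np.log(1000)))))
            return {"hidden": int(np.clip(h, 2, 1000))}
        if self.family == "svm":
            kernel = str(rng.choice(["linear", "poly", "rbf"]))
            params = {"kernel": kernel, "C": 2.0 ** int(rng.integers(-5, 16))}
            if kernel == "rbf":
                params["gamma"] = 2.0 ** int(rng.integers(-15, 4))
            elif kernel == "poly":
                params["degree"] = int(rng.choice([3, 5, 7, 9]))
            return params
        # rf
        return {
            "criterion": str(rng.choice(["gini", "entropy"])),
            "min_samples_split": int(rng.integers(2, 7)),
            "min_samples_leaf": int(rng.integers(1, 7)),
            "n_estimators": self.n_estimators,
        }

    def build(self, params: dict, random_state: int = 0):
        """Instantiate the scikit-learn estimator for one parameter draw."""
        if self.family == "nb":
            return GaussianNB()
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=params["k"])
        if self.family == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(params["hidden"],),
                max_iter=self.mlp_max_iter,
                random_state=random_state,
            )
        if self.family == "svm":
            kwargs = {
                "kernel": params["kernel"],
                "C": params["C"],
                "max_iter": self.svm_max_iter,
            }
            if params["kernel"] == "rbf":
                kwargs["gamma"] = params["gamma"]
            elif params["kernel"] == "poly":
                kwargs["degree"] = params["degree"]
            return SVC(**kwargs)
        return RandomForestClassifier(
            criterion=params["criterion"],
            min_samples_split=params["min_samples_split"],
            min_samples_leaf=params["min_samples_leaf"],
            n_estimators=params["n_estimators"],
            random_state=random_state,
        )


def random_search(
    space: HyperparamSpace,
    features: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 20,
    inner_folds: int = 10,
    seed: int = 0,
) -> dict:
    """Pick the parameter draw with the best mean inner-CV accuracy.

    ``n_iter`` draws from the family's domains are each scored by
    stratified ``inner_folds``-fold cross-validated accuracy on
    (features, labels); ties keep the first candidate encountered.
    Deterministic for a fixed seed. Families without hyperparameters
    return immediately.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if space.family == "nb":
        return {}
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() < inner_folds:
        raise ConfigurationError(
            f"need >= {inner_folds} samples per class for {inner_folds}-fold "
            f"inner CV; smallest class has {class_counts.min()}"
        )
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                         random_state=int(rng.integers(2**31)))
    best_params, best_score = None, -np.inf
    for _ in range(n_iter):
        params = space.sample(rng)
        model_seed = int(rng.integers(2**31))
        scores = []
        for train_idx, test_idx in cv.split(features, labels):
            model = space.build(params, random_state=model_seed)
            model.fit(features[train_idx], labels[train_idx])
            scores.append(
                float(np.mean(model.predict(features[test_idx]) == labels[test_idx]))
            )
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


@dataclass
class EvalResult:
    """Per-split macro metrics (percent) with their summary statistics."""

    family: str
    per_split: dict[str, list[float]]  # metric name -> one value per split
    chosen_params: list[dict]
    seeds: list[int]

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_split[metric]))

    def std(self, metric: str) -> float:
        return float(np.std(self.per_split[metric]))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m)) for m in METRIC_NAMES}

    def format_summary(self) -> str:
        parts = [
            f"{m}: {self.mean(m):.2f} ± {self.std(m):.2f}" for m in METRIC_NAMES
        ]
        return f"{self.family}: " + ", ".join(parts)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "per_split": self.per_split,
            "summary": {
                m: {"mean": self.mean(m), "std": self.std(m)} for m in METRIC_NAMES
            },
            "chosen_params": self.chosen_params,
            "seeds": self.seeds,
        }


def evaluate(
    features: np.ndarray,
    labels: Sequence,
    family: str,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    n_iter: int = 20,
    inner_folds: int = 10,
    space: HyperparamSpace | None = None,
) -> EvalResult:
    """Repeated stratified 80/20 evaluation with inner random search.

    For each of ``n_splits`` stratified random splits: random-search the
    hyperparameters on the training portion, refit, and compute macro
    metrics on the held-out portion. Returns per-split metrics in
    percent plus the chosen parameters and derived seeds.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray([str(y) for y in labels])
    if features.ndim != 2 or features.shape[0] != labels.size:
        raise ConfigurationError("features must be (n_samples, n_features) matching labels")
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ConfigurationError("both classes must be present")
    if class_counts.min() < 2:
        raise ConfigurationError(
            f"every class needs >= 2 samples; smallest has {class_counts.min()}"
        )
    space = space or HyperparamSpace(family)
    if space.family != family:
        raise ConfigurationError(
            f"space family {space.family!r} does not match requested {family!r}"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    rng = np.random.default_rng(seed)
    per_split = {m: [] for m in METRIC_NAMES}
    chosen: list[dict] = []
    seeds: list[int] = []
    for train_idx, test_idx in splitter.split(features, labels):
        split_seed = int(rng.integers(2**31))
        seeds.append(split_seed)
        params = random_search(
            space, features[train_idx], labels[train_idx],
            n_iter=n_iter, inner_folds=inner_folds, seed=split_seed,
        )
        model = space.build(params if params else {}, random_state=split_seed)
        model.fit(features[train_idx], labels[train_idx])
        predictions = model.predict(features[test_idx])
        counts = confusion(labels[test_idx], predictions, classes=list(classes))
        acc, prec, rec, f1 = macro_metrics(counts)
        for name, value in zip(METRIC_NAMES, (acc, prec, rec, f1)):
            per_split[name].append(value)
        chosen.append(params)
    return EvalResult(family=family, per_split=per_split, chosen_params=chosen, seeds=seeds)
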