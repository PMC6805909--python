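"""Classification and evaluation protocol.

Repeated stratified holdout: 70% of each class to train, the rest to
test, 30 independent repetitions, classifying with k-NN (majority vote,
nearest-member tie-break) or a random forest, and scoring accuracy plus
micro- and macro-averaged F1 from the confusion matrix.  Means come with
Student-t 95% confidence-interval half-widths over the repetitions.

Micro-F1 is computed from the class-summed true positives, false
positives and false negatives:

    F1_micro = 2 sum TP_i / (2 sum TP_i + sum FP_i + sum FN_i)

In single-label multiclass classification this is identical to accuracy
(every off-diagonal count is one FP and one FN), so macro-F1 is reported
alongside as the averaging that can actually differ from accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_REPETITIONS = 30

FEATURE_KINDS = {"colour": 12, "shape": 144, "texture": 10, "combined": 166}


@dataclass(frozen=True)
class FeatureTable:
    """One feature vector per specimen, plus its label."""

    species: np.ndarray  # (n,) str
    sample_ids: np.ndarray  # (n,) str
    values: np.ndarray  # (n, d) float
    feature_kind: str = "combined"

    def __post_init__(self) -> None:
        if self.feature_kind in FEATURE_KINDS:
            expected = FEATURE_KINDS[self.feature_kind]
            if self.values.shape[1] != expected:
                raise ValueError(
                    f"{self.feature_kind} features must have {expected} columns, "
                    f"got {self.values.shape[1]}"
                )
        if not (len(self.species) == len(self.sample_ids) == len(self.values)):
            raise ValueError("species, sample_ids and values must align")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.species[idx], self.sample_ids[idx],
                            self.values[idx], self.feature_kind)

    def to_frame(self, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(feature_names) if feature_names is not None else [
            f"f{i:03d}" for i in range(self.values.shape[1])
        ]
        df = pd.DataFrame(self.values, columns=names)
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(0, "species", self.species)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_kind: str = "combined") -> "FeatureTable":
        feats = df.drop(columns=["species", "sample_id"])
        return cls(df["species"].to_numpy(str), df["sample_id"].to_numpy(str),
                   feats.to_numpy(float), feature_kind)


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), rows true, cols predicted
    labels: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred, strict=True):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def micro_f1(cm: ConfusionMatrix) -> float:
    """Class-summed F1: 2*TP / (2*TP + FP + FN)."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).sum()
    fp = (cm.counts.sum(axis=0) - np.diag(cm.counts)).sum()
    fn = (cm.counts.sum(axis=1) - np.diag(cm.counts)).sum()
    return float(2 * tp / (2 * tp + fp + fn))


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1; a class with no support and no
    predictions contributes 0."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm.counts).astype(float)
    fp = cm.counts.sum(axis=0) - tp
    fn = cm.counts.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    f1 = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    return float(f1.mean())


def stratified_split(
    table: FeatureTable,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int | np.random.Generator = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Per class, round(train_fraction * n_c) samples to train, rest to test.

    With 10 samples per class and the default fraction this is exactly
    7 train / 3 test.  Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in np.unique(table.species):
        idx = np.nonzero(table.species == label)[0]
        if len(idx) < 2:
            raise ValueError(
                f"class {label!r} has only {len(idx)} sample(s); cannot split"
            )
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


def knn_predict(
    train: FeatureTable, test: FeatureTable, k: int = 1, metric: str = "euclidean"
) -> np.ndarray:
    """Majority vote among the k nearest training vectors.

    A vote tie is broken in favour of the tied class whose nearest member
    is closest to the query.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(train):
        raise ValueError(f"k={k} exceeds training-set size {len(train)}")
    d = cdist(test.values, train.values, metric=metric)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    preds = np.empty(len(test), dtype=train.species.dtype)
    for i in range(len(test)):
        neigh = order[i]
        labels = train.species[neigh]
        uniq, counts = np.unique(labels, return_counts=True)
        best = counts.max()
        tied = set(uniq[counts == best])
        if len(tied) == 1:
            preds[i] = next(iter(tied))
        else:
            # neigh is sorted by distance: first member of a tied class wins
            preds[i] = next(lab for lab in labels if lab in tied)
    return preds


def rf_predict(
    train: FeatureTable,
    test: FeatureTable,
    n_trees: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Random forest: bagged trees with sqrt(d) features per split, mode vote."""
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=int(seed), n_jobs=1
    )
    clf.fit(train.values, train.species)
    return clf.predict(test.values).astype(train.species.dtype)


def mean_ci(values: Sequence[float], confidence: float = 0.95) -> tuple[float, float]:
    """Mean and Student-t confidence-interval half-width of repeated metrics."""
    v = np.asarray(values, dtype=float)
    if len(v) == 1:
        warnings.warn("single repetition: confidence interval undefined, reporting 0")
        return float(v[0]), 0.0
    sd = v.std(ddof=1)
    t = stats.t.ppf(0.5 + confidence / 2.0, len(v) - 1)
    return float(v.mean()), float(t * sd / np.sqrt(len(v)))


@dataclass(frozen=True)
class EvalResult:
    """Per-metric mean and 95% CI half-width over repetitions."""

    metrics: dict[str, tuple[float, float]]  # name -> (mean, ci95 half-width)
    repetitions: int
    params: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return self.metrics[name][0]

    def ci(self, name: str) -> float:
        return self.metrics[name][1]


ClassifierFn = Callable[[FeatureTable, FeatureTable, np.random.Generator], np.ndarray]


def make_classifier(name: str, **params) -> ClassifierFn:
    """'knn' (param k) or 'rf' (param n_trees) as a split->predictions callable."""
    if name == "knn":
        k = int(params.get("k", 1))
        return lambda tr, te, rng: knn_predict(tr, te, k=k)
    if name == "rf":
        n_trees = int(params.get("n_trees", 100))
        return lambda tr, te, rng: rf_predict(
            tr, te, n_trees=n_trees, seed=int(rng.integers(2**31))
        )
    raise ValueError(f"unknown classifier {name!r}")


def repeat_eval(
    table: FeatureTable,
    classifier: ClassifierFn,
    repetitions: int = DEFAULT_REPETITIONS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    split_hook: Callable | None = None,
) -> EvalResult:
    """Repeatedly split, fit, predict and score; aggregate with t-CIs.

    ``split_hook(train, test, rng) -> (train, test)`` can post-process each
    split, e.g. to refit the texture PCA on the training rows only.
    """
    ss = np.random.SeedSequence(seed)
    per_metric: dict[str, list[float]] = {"accuracy": [], "micro_f1": [], "macro_f1": []}
    labels = sorted(np.unique(table.species))
    for child in ss.spawn(repetitions):
        rng = np.random.default_rng(child)
        train, test = stratified_split(table, train_fraction, seed=rng)
        if split_hook is not None:
            train, test = split_hook(train, test, rng)
        preds = classifier(train, test, rng)
        cm = confusion_matrix(test.species, preds, labels=labels)
        per_metric["accuracy"].append(accuracy(cm))
        per_metric["micro_f1"].append(micro_f1(cm))
        per_metric["macro_f1"].append(macro_f1(cm))
    return EvalResult(
        metrics={k: mean_ci(v) for k, v in per_metric.items()},
        repetitions=repetitions,
    )


def parameter_sweep(
    table: FeatureTable,
    classifier_name: str,
    grid: Sequence[int],
    param: str | None = None,
    repetitions: int = DEFAULT_REPETITIONS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[list[EvalResult], int]:
    """repeat_eval at each grid point; returns the curve and the grid value
    with the highest mean accuracy."""
    if len(grid) == 0:
        raise ValueError("parameter grid must be non-empty")
    param = param or {"knn": "k", "rf": "n_trees"}[classifier_name]
    curve = []
    for value in grid:
        clf = make_classifier(classifier_name, **{param: value})
        res = repeat_eval(table, clf, repetitions=repetitions,
                         train_fraction=train_fraction, seed=seed)
        curve.append(EvalResult(res.metrics, res.repetitions, {param: value}))
    best = int(grid[int(np.argmax([r.mean("accuracy") for r in curve]))])
    return curve, best
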