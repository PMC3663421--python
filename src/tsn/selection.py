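"""Feature pre-selection, dynamic classifier-size choice, cross-validation, MCC.

Feature pools are chosen per classifier size N by a two-sided Wilcoxon
rank-sum test of each feature's expression between the two classes, with
per-N budgets (default 16/10/9 features for N = 2/3/4) that equalise the
number of candidate combinations across sizes at roughly 120.

Dynamic N refits the classifier for every candidate size on the training
portion alone and keeps the size with the best apparent (resubstitution)
accuracy, ties going to the smallest size; performing this inside every
cross-validation fold avoids the optimistic bias of choosing N after
seeing test performance.

Evaluation follows the Matthews correlation coefficient (MCC), with the
convention that a zero factor in the denominator sets the denominator to
one (yielding MCC = 0, since a zero marginal forces a zero numerator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import UNRESOLVED, Prediction, accuracy, predict
from .core import TsnClassifier, rank_transform, search_top_classifier

#: Per-N feature budgets equalising the candidate combination space:
#: C(16,2) = 120, C(10,3) = 120, C(9,4) = 126.
DEFAULT_DEG_BUDGET = {2: 16, 3: 10, 4: 9}


@dataclass(frozen=True)
class DynamicNConfig:
    """Candidate classifier sizes and per-size feature budgets."""

    n_values: tuple[int, ...] = (2, 3, 4)
    deg_budget: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_DEG_BUDGET)
    )

    def __post_init__(self) -> None:
        if not self.n_values:
            raise ValueError("at least one candidate size N is required")
        object.__setattr__(self, "n_values", tuple(sorted(set(self.n_values))))
        for n in self.n_values:
            if n < 2:
                raise ValueError(f"classifier size must be >= 2, got {n}")
            if n not in self.deg_budget:
                raise ValueError(f"no feature budget given for N={n}")
            if self.deg_budget[n] < n:
                raise ValueError(
                    f"budget {self.deg_budget[n]} for N={n} is below N"
                )

    def combinations(self, n: int) -> int:
        return math.comb(self.deg_budget[n], n)


def wilcoxon_scores(
    values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature two-sided Wilcoxon rank-sum z and p (normal approximation).

    Uses midranks, the tie-corrected variance, and a 0.5 continuity
    correction toward the null.  ``values`` is features x samples.
    """
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes need at least one sample")
    n = n1 + n2
    ranks = stats.rankdata(values, axis=1)
    u = ranks[:, mask1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # tie correction: sum over tied groups of (t^3 - t), per feature
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = float(((counts**3) - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))

    diff = u - mu
    numer = diff - 0.5 * np.sign(diff)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, numer / np.where(sigma > 0, sigma, 1.0), 0.0)
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return z, p


def wilcoxon_rank_select(matrix: pd.DataFrame, labels, k: int) -> list[str]:
    """The k most differentially expressed features by Wilcoxon rank-sum p-value.

    Returns feature ids ordered by ascending p; ties are broken by larger
    |z|, then by feature input order.
    """
    m = matrix.shape[0]
    if k > m:
        raise ValueError(f"cannot select k={k} features from {m}")
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = pd.Series(labels).reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, found {len(classes)}")
    y = labels.to_numpy()
    z, p = wilcoxon_scores(
        matrix.to_numpy(dtype=float), y == classes[0], y == classes[1]
    )
    order = np.lexsort((np.arange(m), -np.abs(z), p))
    return [str(matrix.index[i]) for i in order[:k]]


def apparent_accuracy(
    matrix: pd.DataFrame, labels, n: int, config: DynamicNConfig
) -> tuple[TsnClassifier, float]:
    """Fit the top size-n classifier and score it back on its own training data.

    Selects the per-N Wilcoxon feature pool, searches exhaustively, then
    reclassifies the training samples (resubstitution).
    """
    pool = wilcoxon_rank_select(matrix, labels, min(config.deg_budget[n], matrix.shape[0]))
    ranked = rank_transform(matrix, labels)
    clf = search_top_classifier(ranked, n, pool)
    preds = predict(clf, matrix)
    labels = pd.Series(labels).reindex(matrix.columns)
    return clf, accuracy(preds, list(labels))


def dynamic_n_fit(
    matrix: pd.DataFrame, labels, config: DynamicNConfig | None = None
) -> tuple[int, TsnClassifier]:
    """Choose the classifier size by apparent accuracy on the training data.

    Every candidate N gets its own Wilcoxon pool and exhaustive search;
    the N with the highest apparent accuracy wins, ties going to the
    smallest tied N.
    """
    config = config or DynamicNConfig()
    best: tuple[float, int, TsnClassifier] | None = None
    for n in config.n_values:  # ascending, so strict > keeps the smallest tie
        clf, acc = apparent_accuracy(matrix, labels, n, config)
        if best is None or acc > best[0]:
            best = (acc, n, clf)
    assert best is not None
    return best[1], best[2]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with an explicit positive-class convention."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @classmethod
    def from_predictions(
        cls,
        predictions: Sequence[Prediction],
        true_labels: Sequence[str],
        positive: str,
    ) -> "ConfusionCounts":
        """Tally predictions; an UNRESOLVED prediction is scored as a miss
        (FN when the truth is positive, FP otherwise)."""
        if len(predictions) != len(true_labels):
            raise ValueError("predictions and labels differ in length")
        tp = tn = fp = fn = 0
        for pred, truth in zip(predictions, true_labels):
            truth_pos = truth == positive
            if pred.label == UNRESOLVED:
                if truth_pos:
                    fn += 1
                else:
                    fp += 1
            elif pred.label == truth:
                if truth_pos:
                    tp += 1
                else:
                    tn += 1
            elif truth_pos:
                fn += 1
            else:
                fp += 1
        return cls(tp, tn, fp, fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    If any marginal sum in the denominator is zero, the denominator is set
    to one; the numerator is then necessarily zero, so MCC = 0.
    """
    numer = c.tp * c.tn - c.fp * c.fn
    factors = (c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn)
    if 0 in factors:
        return float(numer)  # a zero marginal forces numer == 0
    return numer / math.sqrt(math.prod(float(f) for f in factors))


def delta_mcc(cv_mcc: float, validation_mcc: float) -> float:
    """Overfitting gap |cross-validation MCC - validation-set MCC|."""
    for v in (cv_mcc, validation_mcc):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"MCC values must lie in [-1, 1], got {v}")
    return abs(cv_mcc - validation_mcc)


@dataclass(frozen=True)
class FoldRecord:
    """Everything fitted and predicted in one cross-validation fold."""

    repeat: int
    fold: int
    chosen_n: int
    features: tuple[str, ...]
    delta: float
    gamma: int
    test_samples: tuple[str, ...]
    true_labels: tuple[str, ...]
    predictions: tuple[Prediction, ...]


@dataclass(frozen=True)
class CvReport:
    """Aggregated repeated k-fold cross-validation results."""

    folds: tuple[FoldRecord, ...]
    positive_class: str
    class_labels: tuple[str, str]
    accuracies: tuple[float, ...]  # one per repeat, pooled over folds
    mccs: tuple[float, ...]  # one per repeat
    confusion: ConfusionCounts  # pooled over all repeats and folds
    n_folds: int
    n_repeats: int
    seed: int
    stratified: bool

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.mccs))

    def to_dict(self) -> dict:
        return {
            "positive_class": self.positive_class,
            "class_labels": list(self.class_labels),
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "stratified": self.stratified,
            "mean_accuracy": self.mean_accuracy,
            "mean_mcc": self.mean_mcc,
            "accuracy_per_repeat": list(self.accuracies),
            "mcc_per_repeat": list(self.mccs),
            "pooled_confusion": {
                "TP": self.confusion.tp,
                "TN": self.confusion.tn,
                "FP": self.confusion.fp,
                "FN": self.confusion.fn,
            },
            "folds": [
                {
                    "repeat": f.repeat,
                    "fold": f.fold,
                    "chosen_n": f.chosen_n,
                    "features": list(f.features),
                    "delta": f.delta,
                    "gamma": f.gamma,
                    "test_samples": list(f.test_samples),
                    "true_labels": list(f.true_labels),
                    "predicted_labels": [p.label for p in f.predictions],
                    "resolution_depths": [p.resolution_depth for p in f.predictions],
                }
                for f in self.folds
            ],
        }


def repeat_seeds(seed: int, repeats: int) -> list[int]:
    """Deterministic per-repeat integer seeds (< 2^31) from one user seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s % (2**31)) for s in ss.generate_state(repeats, dtype=np.uint64)]


def cross_validate(
    matrix: pd.DataFrame,
    labels,
    folds: int = 5,
    repeats: int = 10,
    config: DynamicNConfig | None = None,
    n: int | None = None,
    seed: int = 0,
    stratify: bool = True,
    positive_class: str | None = None,
) -> CvReport:
    """Repeated k-fold cross-validation with in-fold feature and N selection.

    Every repeat draws a fresh seeded (by default stratified) fold
    assignment.  Within each fold, Wilcoxon feature selection and the
    classifier-size choice use the training portion only; the held-out
    fold is scored with the fitted classifier.  ``n`` fixes the classifier
    size; otherwise the dynamic-N protocol runs over ``config.n_values``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    config = config or DynamicNConfig()
    if n is not None:
        config = replace(config, n_values=(n,))

    labels = pd.Series(labels).reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    y = labels.to_numpy()
    class_labels = []
    for v in y:
        if v not in class_labels:
            class_labels.append(v)
    if len(class_labels) != 2:
        raise ValueError(f"exactly two classes required, found {len(class_labels)}")
    class_labels = (class_labels[0], class_labels[1])
    positive = positive_class if positive_class is not None else class_labels[0]
    if positive not in class_labels:
        raise ValueError(f"positive class {positive!r} is not a label")
    smallest = min(int((y == c).sum()) for c in class_labels)
    if smallest < folds:
        raise ValueError(
            f"smallest class has {smallest} samples, fewer than {folds} folds"
        )

    records: list[FoldRecord] = []
    accuracies: list[float] = []
    mccs: list[float] = []
    pooled = ConfusionCounts()
    dummy_x = np.zeros((matrix.shape[1], 1))

    for repeat, rep_seed in enumerate(repeat_seeds(seed, repeats)):
        splitter = (
            StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
            if stratify
            else KFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        )
        repeat_preds: list[Prediction] = []
        repeat_truth: list[str] = []
        for fold, (train_idx, test_idx) in enumerate(splitter.split(dummy_x, y)):
            train_matrix = matrix.iloc[:, train_idx]
            train_labels = labels.iloc[train_idx]
            chosen_n, clf = dynamic_n_fit(train_matrix, train_labels, config)
            test_matrix = matrix.iloc[:, test_idx]
            preds = predict(clf, test_matrix)
            truth = [str(t) for t in labels.iloc[test_idx]]
            records.append(
                FoldRecord(
                    repeat=repeat,
                    fold=fold,
                    chosen_n=chosen_n,
                    features=clf.features,
                    delta=clf.delta,
                    gamma=clf.gamma,
                    test_samples=tuple(str(s) for s in test_matrix.columns),
                    true_labels=tuple(truth),
                    predictions=tuple(preds),
                )
            )
            repeat_preds.extend(preds)
            repeat_truth.extend(truth)
        accuracies.append(accuracy(repeat_preds, repeat_truth))
        conf = ConfusionCounts.from_predictions(repeat_preds, repeat_truth, positive)
        mccs.append(mcc(conf))
        pooled = pooled + conf

    return CvReport(
        folds=tuple(records),
        positive_class=str(positive),
        class_labels=(str(class_labels[0]), str(class_labels[1])),
        accuracies=tuple(accuracies),
        mccs=tuple(mccs),
        confusion=pooled,
        n_folds=folds,
        n_repeats=repeats,
        seed=int(seed),
        stratified=stratify,
    )
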