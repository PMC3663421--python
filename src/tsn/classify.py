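"""Prediction with a fitted TSN classifier.

A test sample's within-sample ordering of the classifier's N features is
encoded to a permutation index; the predicted class is the one with the
higher training permutation probability at that index.  When the two
class probabilities are exactly equal (including both zero), a maximum-
likelihood fallback sums the probabilities over all permutations at
inversion distance 1 from the sample's permutation, then distance 2, and
so on, until the sums differ.  If every shell ties — possible only when
the two class distributions are identical — the sample is UNRESOLVED and
is always counted as an incorrect prediction.

Probability comparisons are done in exact integer arithmetic
(cross-multiplied counts), never with a floating tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TsnClassifier, _encode_orderings
from .permutations import neighbors_at_distance, permutation_diameter

#: Label given to samples the fallback cannot resolve.
UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class Prediction:
    """One sample's predicted label.

    ``resolution_depth`` is 0 when the direct histogram comparison decided,
    d when the tie was resolved at the inversion-distance-d shell, and the
    permutation diameter N(N-1)/2 for UNRESOLVED samples.
    """

    sample_id: str
    label: str
    resolution_depth: int


def _decide(model: TsnClassifier, perm_index: int, sample_id: str) -> Prediction:
    c1 = model.hist1.counts
    c2 = model.hist2.counts
    n1 = model.hist1.n_samples
    n2 = model.hist2.n_samples
    a = int(c1[perm_index]) * n2
    b = int(c2[perm_index]) * n1
    if a != b:
        label = model.class_labels[0] if a > b else model.class_labels[1]
        return Prediction(sample_id, label, 0)
    diameter = permutation_diameter(model.n)
    for d in range(1, diameter + 1):
        shell = sorted(neighbors_at_distance(perm_index, model.n, d))
        a = int(c1[shell].sum()) * n2
        b = int(c2[shell].sum()) * n1
        if a != b:
            label = model.class_labels[0] if a > b else model.class_labels[1]
            return Prediction(sample_id, label, d)
    return Prediction(sample_id, UNRESOLVED, diameter)


def predict_sample(
    model: TsnClassifier,
    sample: Mapping[str, float] | pd.Series,
    sample_id: str = "sample",
) -> Prediction:
    """Predict one sample from its expression values (or ranks) per feature.

    Only the relative order of the model's features matters, so raw
    values, within-sample ranks, or any rank-preserving transform of them
    give the same prediction.  Ties between features are broken by the
    model's feature order.
    """
    try:
        vals = np.array([float(sample[f]) for f in model.features])
    except KeyError as exc:
        raise ValueError(f"sample is missing feature {exc.args[0]!r}") from None
    idx = int(_encode_orderings(vals[:, None])[0])
    return _decide(model, idx, sample_id)


def predict(model: TsnClassifier, matrix: pd.DataFrame) -> list[Prediction]:
    """Predict every sample column of a features-x-samples matrix.

    Feature ties within a sample are broken by matrix row order, matching
    the tie rule of the rank transform at training time.
    """
    missing = [f for f in model.features if f not in matrix.index]
    if missing:
        raise ValueError(f"matrix is missing model features: {missing}")
    # Order the tuple's rows as they appear in the matrix so that stable
    # sorting ties agree with a full-matrix rank transform.
    positions = {f: matrix.index.get_loc(f) for f in model.features}
    canon = sorted(model.features, key=positions.__getitem__)
    tuple_pos = {f: i for i, f in enumerate(model.features)}
    sub = matrix.loc[list(canon)].to_numpy(dtype=float)
    if not np.isfinite(sub).all():
        raise ValueError("non-finite values among model features")
    order = np.argsort(sub, axis=0, kind="stable")
    mapping = np.array([tuple_pos[f] for f in canon])
    slots = mapping[order] + 1  # N x S permutations in tuple positions
    indices = _encode_orderings_from_slots(slots)
    return [
        _decide(model, int(indices[j]), str(sample_id))
        for j, sample_id in enumerate(matrix.columns)
    ]


def _encode_orderings_from_slots(slots: np.ndarray) -> np.ndarray:
    """Vectorised Lehmer encoding of N x S slot matrices (columns are permutations)."""
    n = slots.shape[0]
    idx = np.zeros(slots.shape[1], dtype=np.int64)
    for i in range(n - 1):
        smaller = np.zeros(slots.shape[1], dtype=np.int64)
        for j in range(i + 1, n):
            smaller += slots[j] < slots[i]
        idx += smaller * math.factorial(n - 1 - i)
    return idx


def accuracy(predictions: Sequence[Prediction], true_labels: Sequence[str]) -> float:
    """Fraction of correct predictions; UNRESOLVED always counts as incorrect."""
    if len(predictions) != len(true_labels):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(true_labels)} labels"
        )
    if not predictions:
        raise ValueError("no predictions to score")
    correct = sum(p.label == t for p, t in zip(predictions, true_labels))
    return correct / len(predictions)
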