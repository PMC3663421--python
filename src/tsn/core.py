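"""Core TSN machinery: within-sample ranks, permutation histograms, scores, search.

The top-scoring 'N' (TSN) classifier generalises the top-scoring pair
(TSP, N=2) and top-scoring triplet (TST, N=3).  For a tuple ``X`` of N
features, each sample's within-sample ordering of the tuple is encoded as
a permutation index in ``[0, N!-1]`` (Lehmer code); accumulating those
indices per class gives two histograms whose normalised forms are the
class-conditional permutation probability distributions.  The primary
score is half the L1 distance between the two distributions,

    delta_X = 1/2 * sum_m | Pr(sigma_m | C1) - Pr(sigma_m | C2) |,

which is 1 exactly when the supports are disjoint and 0 when the
distributions coincide.  A secondary score gamma_X — the rank distance
between the first and last tuple features summed over training samples —
breaks ties in delta in favour of wider rank separation.

Scores are compared in exact integer arithmetic (histogram counts cross-
multiplied by class sizes) so that ties and the final float value are
independent of floating-point summation order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .permutations import CapacityError, MAX_N, encode_permutation


@dataclass(frozen=True)
class RankedDataset:
    """Expression matrix reduced to within-sample ranks plus binary labels.

    ``ranks`` is features x samples; each column is a permutation of
    ``1..M`` (rank 1 = smallest expression in that sample), with ties
    broken deterministically by feature input order.
    """

    ranks: np.ndarray
    labels: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    class_labels: tuple[str, str]

    def __post_init__(self) -> None:
        if self.ranks.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("rank matrix shape does not match identifiers")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_rows(self, features: Sequence[str]) -> np.ndarray:
        """Row indices of ``features``; raises on unknown or repeated ids."""
        if len(set(features)) != len(features):
            raise ValueError(f"features must be distinct, got {tuple(features)}")
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([lookup[f] for f in features], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown feature id {exc.args[0]!r}") from None


def _ordered_class_labels(labels: pd.Series) -> tuple[str, str]:
    seen: list[str] = []
    for v in labels:
        if v not in seen:
            seen.append(v)
    if len(seen) != 2:
        raise ValueError(f"exactly two classes required, found {len(seen)}: {seen}")
    return seen[0], seen[1]


def _align_labels(matrix: pd.DataFrame, labels) -> pd.Series:
    labels = pd.Series(labels)
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:10]}")
    return labels.reindex(matrix.columns)


def rank_transform(matrix: pd.DataFrame, labels) -> RankedDataset:
    """Replace every sample column of ``matrix`` by within-sample ranks.

    Rank 1 is the lowest expression in the column.  Ties are broken by
    feature input order (the first-listed feature takes the lower rank) so
    that every column is a strict permutation of ``1..M``.

    Parameters
    ----------
    matrix : DataFrame, features x samples, numeric, finite.
    labels : mapping or Series, sample id -> class label (exactly two
        distinct labels; the first label encountered along the columns is
        stored first in ``class_labels``).
    """
    values = matrix.to_numpy(dtype=float)
    m, s = values.shape
    if m < 2 or s < 2:
        raise ValueError(f"need at least 2 features and 2 samples, got {m}x{s}")
    bad = ~np.isfinite(values)
    if bad.any():
        cells = [
            (matrix.index[i], matrix.columns[j])
            for i, j in zip(*np.nonzero(bad))
        ][:10]
        raise ValueError(f"non-finite expression values at (feature, sample): {cells}")
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")

    aligned = _align_labels(matrix, labels)
    class_labels = _ordered_class_labels(aligned)

    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty((m, s), dtype=np.int64)
    np.put_along_axis(ranks, order, np.arange(1, m + 1)[:, None], axis=0)
    return RankedDataset(
        ranks=ranks,
        labels=aligned.to_numpy(dtype=object),
        feature_ids=tuple(str(f) for f in matrix.index),
        sample_ids=tuple(str(c) for c in matrix.columns),
        class_labels=class_labels,
    )


def _encode_orderings(sub: np.ndarray) -> np.ndarray:
    """Permutation index per sample for the N x S rank (or value) block ``sub``.

    The permutation for a sample lists the 1-based tuple positions in
    ascending order of their ranks; its Lehmer/factoradic index is
    computed vectorised over samples.
    """
    n = sub.shape[0]
    order = np.argsort(sub, axis=0, kind="stable")
    idx = np.zeros(sub.shape[1], dtype=np.int64)
    for i in range(n - 1):
        smaller = np.zeros(sub.shape[1], dtype=np.int64)
        for j in range(i + 1, n):
            smaller += order[j] < order[i]
        idx += smaller * math.factorial(n - 1 - i)
    return idx


@dataclass(frozen=True)
class PermutationHistogram:
    """Counts of sample permutation indices for one class; length N!."""

    counts: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1 or (counts < 0).any():
            raise ValueError("counts must be a 1-d non-negative vector")
        if int(counts.sum()) != self.n_samples:
            raise ValueError("histogram counts must sum to n_samples")

    @property
    def probabilities(self) -> np.ndarray:
        if self.n_samples == 0:
            raise ValueError("cannot normalise an empty histogram")
        return self.counts / self.n_samples


def sample_permutation(
    ranked: RankedDataset, features: Sequence[str], sample: str
) -> int:
    """Permutation index of ``features`` within one sample.

    The permutation lists the tuple positions ``1..N`` of the features in
    ascending order of their within-sample ranks; e.g. ranks (9, 1, 4) for
    a tuple (a, b, c) order as b < c < a, the permutation [2, 3, 1].
    """
    rows = ranked.feature_rows(features)
    try:
        col = ranked.sample_ids.index(sample)
    except ValueError:
        raise KeyError(f"unknown sample id {sample!r}") from None
    sub = ranked.ranks[rows, col]
    order = np.argsort(sub, kind="stable")
    return encode_permutation([int(p) + 1 for p in order])


def build_histograms(
    ranked: RankedDataset, features: Sequence[str]
) -> tuple[PermutationHistogram, PermutationHistogram]:
    """Class-conditional permutation histograms for a feature tuple."""
    rows = ranked.feature_rows(features)
    n = len(rows)
    if n > MAX_N:
        raise CapacityError(f"tuple size {n} exceeds the size guard MAX_N={MAX_N}")
    nfact = math.factorial(n)
    idx = _encode_orderings(ranked.ranks[rows])
    out = []
    for label in ranked.class_labels:
        mask = ranked.class_mask(label)
        k = int(mask.sum())
        if k == 0:
            raise ValueError(f"class {label!r} has no samples")
        out.append(PermutationHistogram(np.bincount(idx[mask], minlength=nfact), k))
    return out[0], out[1]


def _l1_numerator(h1: PermutationHistogram, h2: PermutationHistogram) -> int:
    """Integer numerator sum_m |c1[m]*n2 - c2[m]*n1| of the TSN score."""
    if len(h1.counts) != len(h2.counts):
        raise ValueError("histograms must have equal length")
    if h1.n_samples == 0 or h2.n_samples == 0:
        raise ValueError("histograms must contain at least one sample each")
    return int(np.abs(h1.counts * h2.n_samples - h2.counts * h1.n_samples).sum())


def tsn_score(h1: PermutationHistogram, h2: PermutationHistogram) -> float:
    """TSN score: half the L1 distance between normalised histograms, in [0, 1].

    Computed as an exact integer numerator followed by a single float
    division, so equal scores are exactly equal.  Reduces to the TSP score
    |Pr(x_i < x_j | C1) - Pr(x_i < x_j | C2)| for N = 2 and to the TST
    score for N = 3.
    """
    return _l1_numerator(h1, h2) / (2 * h1.n_samples * h2.n_samples)


def gamma_score(ranked: RankedDataset, features: Sequence[str]) -> int:
    """Secondary score: rank distance between the first and last tuple features.

    Sum over all samples of |rank(last) - rank(first)|; ties in the
    primary score prefer the larger gamma (wider rank separation).
    """
    rows = ranked.feature_rows(features)
    return int(np.abs(ranked.ranks[rows[-1]] - ranked.ranks[rows[0]]).sum())


@dataclass
class TsnClassifier:
    """A fitted size-N relative-expression classifier.

    ``hist1``/``hist2`` hold the raw class-conditional permutation counts
    for ``class_labels[0]``/``class_labels[1]``; ``delta`` and ``gamma``
    are the primary and secondary training scores.
    """

    features: tuple[str, ...]
    n: int
    hist1: PermutationHistogram
    hist2: PermutationHistogram
    class_labels: tuple[str, str]
    delta: float
    gamma: int

    def __post_init__(self) -> None:
        if len(self.features) != self.n or len(set(self.features)) != self.n:
            raise ValueError("features must be n distinct identifiers")
        if len(self.hist1.counts) != math.factorial(self.n):
            raise ValueError("histogram length must be n!")


def fit_classifier(ranked: RankedDataset, features: Sequence[str]) -> TsnClassifier:
    """Build the classifier for one fixed feature tuple."""
    h1, h2 = build_histograms(ranked, features)
    return TsnClassifier(
        features=tuple(features),
        n=len(features),
        hist1=h1,
        hist2=h2,
        class_labels=ranked.class_labels,
        delta=tsn_score(h1, h2),
        gamma=gamma_score(ranked, features),
    )


#: Refuse exhaustive searches larger than this many elementary operations
#: (combinations x N! histogram bins); the search cost grows as
#: O(N * M^N * N!).
DEFAULT_SEARCH_BUDGET = 100_000_000


def search_top_classifier(
    ranked: RankedDataset,
    n: int,
    pool: Sequence[str] | None = None,
    *,
    search_budget: int = DEFAULT_SEARCH_BUDGET,
    allow_large: bool = False,
    return_ties: bool = False,
):
    """Exhaustively score every N-combination of ``pool``; return the best.

    Combinations (not ordered tuples) are scored; the tuple order of each
    candidate is the pool order.  The winner maximises delta; ties on
    delta are broken by maximal gamma, remaining ties by first occurrence
    in lexicographic combination order over pool positions.

    With ``return_ties=True`` also returns the list of co-optimal tuples
    (equal delta and gamma, including the winner).
    """
    if pool is None:
        pool = list(ranked.feature_ids)
    pool = list(pool)
    if len(set(pool)) != len(pool):
        raise ValueError("pool must contain distinct feature ids")
    if n < 1:
        raise ValueError("classifier size n must be >= 1")
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} features cannot host an n={n} tuple")
    if n > MAX_N:
        raise CapacityError(f"n={n} exceeds the size guard MAX_N={MAX_N}")
    nfact = math.factorial(n)
    n_comb = math.comb(len(pool), n)
    if n_comb * nfact > search_budget and not allow_large:
        raise CapacityError(
            f"search of {n_comb} combinations x {nfact} permutations exceeds the "
            f"budget of {search_budget} operations; the cost grows as O(N*M^N*N!). "
            "Pass allow_large=True to override."
        )

    rows_all = ranked.feature_rows(pool)
    mask1 = ranked.class_mask(ranked.class_labels[0])
    mask2 = ranked.class_mask(ranked.class_labels[1])
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes need at least one sample")

    ranks = ranked.ranks
    best: tuple[int, int, tuple[int, ...]] | None = None  # (numer, gamma, comb)
    best_counts: tuple[np.ndarray, np.ndarray] | None = None
    ties: list[tuple[str, ...]] = []

    for comb in itertools.combinations(range(len(pool)), n):
        rows = rows_all[list(comb)]
        idx = _encode_orderings(ranks[rows])
        c1 = np.bincount(idx[mask1], minlength=nfact)
        c2 = np.bincount(idx[mask2], minlength=nfact)
        numer = int(np.abs(c1 * n2 - c2 * n1).sum())
        if best is not None and numer < best[0]:
            continue
        gamma = int(np.abs(ranks[rows[-1]] - ranks[rows[0]]).sum())
        if best is None or numer > best[0] or gamma > best[1]:
            if best is None or numer > best[0]:
                ties = []
            elif gamma > best[1]:
                ties = []
            best = (numer, gamma, comb)
            best_counts = (c1, c2)
            ties.append(tuple(pool[i] for i in comb))
        elif numer == best[0] and gamma == best[1]:
            ties.append(tuple(pool[i] for i in comb))

    assert best is not None and best_counts is not None
    numer, gamma, comb = best
    features = tuple(pool[i] for i in comb)
    clf = TsnClassifier(
        features=features,
        n=n,
        hist1=PermutationHistogram(best_counts[0], n1),
        hist2=PermutationHistogram(best_counts[1], n2),
        class_labels=ranked.class_labels,
        delta=numer / (2 * n1 * n2),
        gamma=gamma,
    )
    if return_ties:
        return clf, ties
    return clf
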