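"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: permutation ranks
come from sorted enumeration, scores from direct ordering counts in exact
rational arithmetic, and ranks from pandas.
"""

import itertools
import math
from fractions import Fraction

import numpy as np


def class_arrays(matrix, y):
    """(values, mask1, mask2) numpy views for a two-class frame."""
    classes = list(dict.fromkeys(y))
    yarr = np.asarray(list(y))
    return (
        matrix.to_numpy(dtype=float),
        yarr == classes[0],
        yarr == classes[1],
    )


def tsp_oracle(values, mask1, mask2, i, j):
    """TSP score |Pr(x_i<x_j|C1) - Pr(x_i<x_j|C2)| as an exact Fraction."""
    below = values[i] < values[j]
    p1 = Fraction(int(below[mask1].sum()), int(mask1.sum()))
    p2 = Fraction(int(below[mask2].sum()), int(mask2.sum()))
    return abs(p1 - p2)


def tst_oracle(values, mask1, mask2, i, j, k):
    """TST score via the six explicit orderings, as an exact Fraction."""
    a, b, c = values[i], values[j], values[k]
    orderings = [
        (a < b) & (b < c),
        (a < c) & (c < b),
        (b < a) & (a < c),
        (b < c) & (c < a),
        (c < a) & (a < b),
        (c < b) & (b < a),
    ]
    total = Fraction(0)
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    for hit in orderings:
        p1 = Fraction(int(hit[mask1].sum()), n1)
        p2 = Fraction(int(hit[mask2].sum()), n2)
        total += abs(p1 - p2)
    return total / 2


def ordinal_ranks(matrix):
    """Within-sample ranks, ties by feature input order (pandas oracle)."""
    return matrix.rank(axis=0, method="first").to_numpy(dtype=np.int64)


def brute_force_search(matrix, y, n):
    """Best (delta, gamma) over all size-n tuples, by direct enumeration.

    Permutation indices come from a sorted-enumeration lookup; scores are
    exact Fractions; tie-breaks follow delta then gamma then combination
    order (only the winning values are returned).
    """
    perm_index = {
        p: r for r, p in enumerate(sorted(itertools.permutations(range(1, n + 1))))
    }
    values, mask1, mask2 = class_arrays(matrix, y)
    ranks = ordinal_ranks(matrix)
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    n_samples = values.shape[1]
    best = None
    for comb in itertools.combinations(range(values.shape[0]), n):
        counts1 = [0] * math.factorial(n)
        counts2 = [0] * math.factorial(n)
        for s in range(n_samples):
            rs = [ranks[f, s] for f in comb]
            order = sorted(range(n), key=lambda t: rs[t])
            m = perm_index[tuple(t + 1 for t in order)]
            if mask1[s]:
                counts1[m] += 1
            else:
                counts2[m] += 1
        delta = (
            sum(
                abs(Fraction(u, n1) - Fraction(v, n2))
                for u, v in zip(counts1, counts2)
            )
            / 2
        )
        gamma = int(np.abs(ranks[comb[-1]] - ranks[comb[0]]).sum())
        key = (delta, gamma)
        if best is None or key > best:
            best = key
    return best
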