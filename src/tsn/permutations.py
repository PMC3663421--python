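"""Permutation / factoradic / integer codec (Lehmer code) and inversion distances.

A size-``N`` permutation is written as a sequence of the slot labels
``1..N``.  Its Lehmer code is the digit vector ``d`` where ``d[i]`` counts
the elements to the *right* of position ``i`` that are smaller than the
element at ``i``.  Read as a factoradic numeral (positional bases
``(N-1)!, (N-2)!, ..., 1!, 0!``) the digits give the permutation's 0-based
lexicographic rank — an integer in ``[0, N!-1]`` that indexes the
permutation histograms used by the TSN classifier.

The inversion distance between two permutations is the minimum number of
adjacent transpositions converting one into the other; measured from the
identity it equals the sum of the factoradic digits.  Exact distance
shells (all permutations at distance exactly ``d``) are computed by
breadth-first expansion over single adjacent swaps, so shells at different
``d`` are disjoint.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Sequence

#: Largest permutation size accepted by default.  N! histogram bins are
#: materialised downstream, so this guards memory/runtime (8! = 40_320).
MAX_N = 8


class CapacityError(RuntimeError):
    """A request would exceed a configured combinatorial size guard."""


def _as_slots(perm: Sequence[int], max_n: int = MAX_N) -> tuple[int, ...]:
    """Validate and normalise a permutation of the slot labels 1..N."""
    slots = tuple(int(v) for v in perm)
    n = len(slots)
    if n < 1:
        raise ValueError("permutation must have at least one slot")
    if n > max_n:
        raise CapacityError(
            f"permutation size {n} exceeds the size guard MAX_N={max_n}"
        )
    if sorted(slots) != list(range(1, n + 1)):
        raise ValueError(
            f"slots must contain each of 1..{n} exactly once, got {slots}"
        )
    return slots


def to_factoradic(perm: Sequence[int], max_n: int = MAX_N) -> list[int]:
    """Lehmer digit vector of ``perm``.

    ``digits[i]`` is the number of elements right of position ``i`` that
    are smaller than ``perm[i]``; the last digit is always 0.
    """
    slots = _as_slots(perm, max_n)
    n = len(slots)
    return [
        sum(1 for j in range(i + 1, n) if slots[j] < slots[i]) for i in range(n)
    ]


def encode_permutation(perm: Sequence[int], max_n: int = MAX_N) -> int:
    """0-based lexicographic rank of ``perm``, an integer in [0, N!-1]."""
    digits = to_factoradic(perm, max_n)
    n = len(digits)
    return sum(d * math.factorial(n - 1 - i) for i, d in enumerate(digits))


def decode_index(index: int, size: int, max_n: int = MAX_N) -> tuple[int, ...]:
    """Inverse of :func:`encode_permutation`.

    Extracts factoradic digits greedily, then selects slot labels from the
    remaining ordered labels.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    if size > max_n:
        raise CapacityError(f"size {size} exceeds the size guard MAX_N={max_n}")
    index = int(index)
    total = math.factorial(size)
    if not 0 <= index < total:
        raise ValueError(f"index {index} out of range [0, {total - 1}] for size {size}")
    remaining = list(range(1, size + 1))
    slots = []
    for i in range(size):
        base = math.factorial(size - 1 - i)
        digit, index = divmod(index, base)
        slots.append(remaining.pop(digit))
    return tuple(slots)


def inversion_count(perm: Sequence[int], max_n: int = MAX_N) -> int:
    """Number of adjacent swaps turning the identity into ``perm``.

    Equals the sum of the factoradic digits and the number of out-of-order
    pairs.
    """
    return sum(to_factoradic(perm, max_n))


def permutation_diameter(size: int) -> int:
    """Largest possible inversion distance between two size-``size`` permutations."""
    return size * (size - 1) // 2


@lru_cache(maxsize=65536)
def _shells_from(index: int, size: int) -> tuple[frozenset[int], ...]:
    """BFS distance shells (as index sets) around ``index`` in the adjacent-swap graph."""
    start = decode_index(index, size)
    seen = {start}
    frontier = [start]
    shells = [frozenset({index})]
    while frontier:
        nxt = []
        for p in frontier:
            lp = list(p)
            for i in range(size - 1):
                lp[i], lp[i + 1] = lp[i + 1], lp[i]
                q = tuple(lp)
                if q not in seen:
                    seen.add(q)
                    nxt.append(q)
                lp[i], lp[i + 1] = lp[i + 1], lp[i]
        if nxt:
            shells.append(frozenset(encode_permutation(q) for q in nxt))
        frontier = nxt
    return tuple(shells)


def neighbors_at_distance(
    index: int, size: int, d: int, max_n: int = MAX_N
) -> frozenset[int]:
    """All permutation indices at adjacent-swap distance exactly ``d`` from ``index``.

    For ``d = 1`` this is the set of ``N-1`` single adjacent transpositions.
    ``d`` beyond the diameter ``N(N-1)/2`` yields the empty set.  The shell
    never contains ``index`` itself.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if size > max_n:
        raise CapacityError(f"size {size} exceeds the size guard MAX_N={max_n}")
    # range check of index happens inside decode_index via _shells_from
    shells = _shells_from(int(index), int(size))
    if d >= len(shells):
        return frozenset()
    return shells[d]
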