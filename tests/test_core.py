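"""Rank transform, histogram, score, and search tests.

Independent oracles: direct pairwise/triplet ordering counts in exact
rational arithmetic for the reduction equivalences, and a hand-coded
brute-force search for the top tuple.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from tsn.core import (
    PermutationHistogram,
    build_histograms,
    fit_classifier,
    gamma_score,
    rank_transform,
    sample_permutation,
    search_top_classifier,
    tsn_score,
)
from tsn.permutations import CapacityError

from conftest import make_dataset


def small_frame(columns):
    """features x samples frame from a dict sample -> column values."""
    m = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"f{i}" for i in range(m)])


def two_class_labels(frame, n1):
    return pd.Series(
        ["A"] * n1 + ["B"] * (frame.shape[1] - n1), index=frame.columns
    )


class TestRankTransform:
    def test_simple_column(self):
        frame = small_frame({"s0": [5.0, 1.0, 3.0], "s1": [0.1, 0.2, 0.3]})
        ranked = rank_transform(frame, two_class_labels(frame, 1))
        assert ranked.ranks[:, 0].tolist() == [3, 1, 2]
        assert ranked.ranks[:, 1].tolist() == [1, 2, 3]

    def test_ties_broken_by_feature_input_order(self):
        frame = small_frame({"s0": [2.0, 2.0, 7.0], "s1": [1.0, 1.0, 1.0]})
        ranked = rank_transform(frame, two_class_labels(frame, 1))
        assert ranked.ranks[:, 0].tolist() == [1, 2, 3]
        assert ranked.ranks[:, 1].tolist() == [1, 2, 3]

    def test_monotone_transform_leaves_ranks_unchanged(self, rng):
        matrix, y = make_dataset(rng, m=10, n1=5, n2=5)
        ranked = rank_transform(matrix, y)
        transformed = np.exp(matrix * 0.5) + 3.0
        ranked2 = rank_transform(transformed, y)
        assert np.array_equal(ranked.ranks, ranked2.ranks)

    def test_every_column_is_a_strict_permutation(self, rng):
        matrix, y = make_dataset(rng, m=7, n1=4, n2=4)
        matrix.iloc[2] = matrix.iloc[5]  # inject ties
        ranked = rank_transform(matrix, y)
        expected = set(range(1, 8))
        for j in range(matrix.shape[1]):
            assert set(ranked.ranks[:, j].tolist()) == expected

    def test_non_finite_values_rejected_with_cell_report(self):
        frame = small_frame({"s0": [1.0, np.nan, 3.0], "s1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="f1.*s0"):
            rank_transform(frame, two_class_labels(frame, 1))

    def test_label_validation(self, rng):
        matrix, y = make_dataset(rng, m=4, n1=3, n2=3)
        with pytest.raises(ValueError, match="missing"):
            rank_transform(matrix, y.iloc[:-1])
        y3 = y.copy()
        y3.iloc[0] = "C"
        with pytest.raises(ValueError, match="two classes"):
            rank_transform(matrix, y3)


class TestSamplePermutation:
    def frame(self):
        # ranks within each sample are fixed by construction
        frame = pd.DataFrame(
            {"s0": [20.0, 70.0, 10.0, 40.0, 90.0]},
            index=["a", "b", "c", "d", "e"],
        )
        frame["s1"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        return frame

    def test_pair_in_order_maps_to_index_zero(self):
        ranked = rank_transform(self.frame(), {"s0": "A", "s1": "B"})
        # rank(a)=2 < rank(b)=4 in s0
        assert sample_permutation(ranked, ("a", "b"), "s0") == 0
        assert sample_permutation(ranked, ("b", "a"), "s0") == 1

    def test_triplet_ordering(self):
        # tuple (e, c, d): ranks in s0 are (5, 1, 3) -> ascending c < d < e
        # -> permutation [2, 3, 1] -> index 3
        ranked = rank_transform(self.frame(), {"s0": "A", "s1": "B"})
        assert sample_permutation(ranked, ("e", "c", "d"), "s0") == 3

    def test_sorted_tuple_is_identity(self):
        ranked = rank_transform(self.frame(), {"s0": "A", "s1": "B"})
        assert sample_permutation(ranked, ("c", "a", "d"), "s0") == 0

    def test_unknown_ids_raise(self):
        ranked = rank_transform(self.frame(), {"s0": "A", "s1": "B"})
        with pytest.raises(KeyError):
            sample_permutation(ranked, ("a", "zzz"), "s0")
        with pytest.raises(KeyError):
            sample_permutation(ranked, ("a", "b"), "nope")
        with pytest.raises(ValueError):
            sample_permutation(ranked, ("a", "a"), "s0")


class TestHistogramsAndScore:
    def test_disjoint_histograms(self):
        # class A: f0 < f1 always; class B: f1 < f0 always
        frame = small_frame(
            {"s0": [1.0, 2.0], "s1": [1.0, 3.0], "s2": [5.0, 2.0], "s3": [9.0, 4.0]}
        )
        ranked = rank_transform(frame, two_class_labels(frame, 2))
        h1, h2 = build_histograms(ranked, ("f0", "f1"))
        assert h1.counts.tolist() == [2, 0]
        assert h2.counts.tolist() == [0, 2]
        assert tsn_score(h1, h2) == 1.0

    def test_single_sample_classes_give_one_hot_histograms(self):
        frame = small_frame({"s0": [1.0, 2.0], "s1": [4.0, 3.0]})
        ranked = rank_transform(frame, two_class_labels(frame, 1))
        h1, h2 = build_histograms(ranked, ("f0", "f1"))
        assert h1.counts.sum() == 1 and h2.counts.sum() == 1

    def test_score_zero_for_identical_distributions(self):
        h = PermutationHistogram(np.array([2, 3, 1, 0, 0, 0]), 6)
        assert tsn_score(h, h) == 0.0

    def test_half_overlap_by_hand(self):
        h1 = PermutationHistogram(np.array([1, 1]), 2)
        h2 = PermutationHistogram(np.array([0, 2]), 2)
        assert tsn_score(h1, h2) == 0.5

    def test_mismatched_lengths_rejected(self):
        h1 = PermutationHistogram(np.array([1, 1]), 2)
        h2 = PermutationHistogram(np.array([2, 0, 0, 0, 0, 0]), 2)
        with pytest.raises(ValueError):
            tsn_score(h1, h2)

    def test_histogram_counts_validated(self):
        with pytest.raises(ValueError):
            PermutationHistogram(np.array([1, 1]), 3)

    def test_score_bounds_and_class_swap_symmetry(self, rng):
        for _ in range(25):
            matrix, y = make_dataset(rng, m=5, n1=4, n2=6)
            ranked = rank_transform(matrix, y)
            swapped = rank_transform(matrix, y.map({"A": "B", "B": "A"}))
            feats = tuple(rng.choice(matrix.index, size=3, replace=False))
            d1 = tsn_score(*build_histograms(ranked, feats))
            d2 = tsn_score(*build_histograms(swapped, feats))
            assert 0.0 <= d1 <= 1.0
            assert d1 == d2


class TestGamma:
    def test_single_sample_rank_gap(self):
        frame = pd.DataFrame(
            {"s0": np.arange(10, dtype=float), "s1": np.arange(10, dtype=float)},
            index=[f"f{i}" for i in range(10)],
        )
        ranked = rank_transform(frame, {"s0": "A", "s1": "B"})
        # ranks of f0 and f9 are 1 and 10 in each sample
        assert gamma_score(ranked, ("f0", "f9")) == 18  # 9 per sample, 2 samples

    def test_additivity_over_samples(self):
        frame = small_frame(
            {"s0": [1.0, 2, 3, 4, 5], "s1": [5.0, 4, 3, 2, 1]}
        )
        ranked = rank_transform(frame, {"s0": "A", "s1": "B"})
        # |rank(f3)-rank(f0)|: s0 -> |4-1| = 3; s1 -> |2-5| = 3
        assert gamma_score(ranked, ("f0", "f3")) == 6

    def test_gamma_at_least_sample_count_for_distinct_endpoints(self, rng):
        matrix, y = make_dataset(rng, m=6, n1=5, n2=5)
        ranked = rank_transform(matrix, y)
        for feats in itertools.combinations(matrix.index, 2):
            assert gamma_score(ranked, feats) >= matrix.shape[1]


class TestReductionEquivalence:
    def test_histogram_delta_equals_tsp_and_tst_formulas(self, rng):
        from oracles import class_arrays, tsp_oracle, tst_oracle

        for _ in range(40):
            m = int(rng.integers(4, 8))
            matrix, y = make_dataset(
                rng, m=m, n1=int(rng.integers(3, 9)), n2=int(rng.integers(3, 9))
            )
            ranked = rank_transform(matrix, y)
            values, mask1, mask2 = class_arrays(matrix, y)
            i, j, k = (int(v) for v in rng.choice(m, size=3, replace=False))
            fi, fj, fk = matrix.index[i], matrix.index[j], matrix.index[k]
            d2 = tsn_score(*build_histograms(ranked, (fi, fj)))
            assert d2 == float(tsp_oracle(values, mask1, mask2, i, j))
            d3 = tsn_score(*build_histograms(ranked, (fi, fj, fk)))
            assert d3 == float(tst_oracle(values, mask1, mask2, i, j, k))


class TestSearch:
    def test_planted_disjoint_tuple_scores_one(self, rng):
        from tsn.simulate import SyntheticSpec, generate

        matrix, y, truth = generate(
            SyntheticSpec(n1=12, n2=12, m_features=15, n_planted=3,
                          fidelity=1.0, seed=11)
        )
        ranked = rank_transform(matrix, y)
        clf = search_top_classifier(ranked, 3)
        assert clf.delta == 1.0

    def test_maximality_against_random_tuples(self, rng):
        matrix, y = make_dataset(rng, m=12, n1=5, n2=5)
        ranked = rank_transform(matrix, y)
        clf = search_top_classifier(ranked, 2)
        for _ in range(100):
            feats = tuple(rng.choice(matrix.index, size=2, replace=False))
            assert clf.delta >= tsn_score(*build_histograms(ranked, feats))

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_independent_brute_force(self, rng, n):
        from oracles import brute_force_search

        for _ in range(10):
            matrix, y = make_dataset(
                rng, m=int(rng.integers(5, 8)), n1=int(rng.integers(3, 7)),
                n2=int(rng.integers(3, 7)),
            )
            ranked = rank_transform(matrix, y)
            clf = search_top_classifier(ranked, n)
            delta, gamma = brute_force_search(matrix, y, n)
            assert clf.delta == float(delta)
            assert clf.gamma == gamma

    def test_gamma_breaks_delta_ties(self):
        # Four features; pairs (f0,f1) and (f2,f3) both separate perfectly,
        # but (f2,f3) sit at the rank extremes, giving the larger gamma.
        frame = pd.DataFrame(
            {
                "s0": [3.0, 4.0, 1.0, 9.0],
                "s1": [3.0, 4.0, 1.0, 9.0],
                "s2": [4.0, 3.0, 9.0, 1.0],
                "s3": [4.0, 3.0, 9.0, 1.0],
            },
            index=["f0", "f1", "f2", "f3"],
        )
        y = pd.Series(["A", "A", "B", "B"], index=frame.columns)
        ranked = rank_transform(frame, y)
        clf, ties = search_top_classifier(ranked, 2, return_ties=True)
        assert clf.features == ("f2", "f3")
        assert clf.delta == 1.0
        assert ties == [("f2", "f3")]

    def test_pool_and_budget_guards(self, rng):
        matrix, y = make_dataset(rng, m=6, n1=3, n2=3)
        ranked = rank_transform(matrix, y)
        with pytest.raises(ValueError):
            search_top_classifier(ranked, 3, pool=["f0", "f1"])
        with pytest.raises(CapacityError, match="O\\(N\\*M\\^N\\*N!\\)"):
            search_top_classifier(ranked, 3, search_budget=10)
        clf = search_top_classifier(ranked, 3, search_budget=10, allow_large=True)
        assert clf.n == 3

    def test_rank_invariance_of_fit(self, rng):
        matrix, y = make_dataset(rng, m=8, n1=6, n2=6)
        ranked = rank_transform(matrix, y)
        clf = search_top_classifier(ranked, 2)
        # a different strictly increasing transform per sample column
        transformed = matrix.copy()
        for j, col in enumerate(transformed.columns):
            x = transformed[col]
            transformed[col] = x**3 if j % 2 else np.exp(0.7 * x) + j
        clf2 = search_top_classifier(rank_transform(transformed, y), 2)
        assert clf.features == clf2.features
        assert clf.delta == clf2.delta
        assert clf.gamma == clf2.gamma

    def test_fit_classifier_delta_recomputable_from_histograms(self, rng):
        matrix, y = make_dataset(rng, m=6, n1=5, n2=5)
        ranked = rank_transform(matrix, y)
        clf = fit_classifier(ranked, ("f1", "f4", "f2"))
        assert clf.delta == tsn_score(clf.hist1, clf.hist2)
        assert clf.gamma == gamma_score(ranked, clf.features)
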