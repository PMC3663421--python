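# Methods

## Model

A TSN classifier of size N over features X = (x_1, …, x_N) reduces each
sample to the permutation describing the within-sample rank order of X.
Permutations are identified with integers 0 … N!−1 by the Lehmer code:
digit i of the factoradic is the count of elements right of position i
that are smaller, and the digit vector is read in the mixed-radix bases
(N−1)!, …, 1!, 0!. This is the unique digit convention consistent with the
worked values the codec is anchored on (the size-4 permutation [3 4 1 2]
has index 16, factoradic [2 2 0 0], four inversions, and single-inversion
neighbors {13, 17, 22}); both directions of the codec and the
lexicographic-rank identity are verified exhaustively for N ≤ 6 in the
test suite.

Training accumulates one histogram of permutation indices per class;
normalising by class size gives the class-conditional permutation
probability distributions. The primary score is half the L1 distance
between them:

    Δ_X = ½ Σ_m | Pr(σ_m|C1) − Pr(σ_m|C2) | ∈ [0, 1],

with Δ_X = 1 exactly when the supports are disjoint. The N = 2 and N = 3
cases coincide with the TSP and TST scores, and the test suite asserts
this equality *exactly* (not to a tolerance) against direct
ordering-count oracles in rational arithmetic.

The secondary score γ_X = Σ_samples |R(X_N) − R(X_1)| (rank distance
between the first and last tuple features, summed over training samples)
breaks Δ ties in favour of wider rank separation. Two readings of γ are
possible — signed vs. absolute per-sample differences, and tuple endpoints
vs. per-sample extreme ranks. We use the **absolute difference between the
tuple's first and last features**: a tie-break must be non-negative to
mean "distance", and the tuple reading keeps γ independent of each
sample's permutation. The choice is isolated in `gamma_score`. Tuple order
itself is the pool order (descending differential-expression evidence);
Δ is invariant to tuple reordering, so this convention only affects γ and
reporting. Remaining ties fall back to the first combination in
lexicographic order over pool positions, for determinism.

## Scoring arithmetic

All score comparisons — Δ during the search, probability comparisons at
prediction time, and the tie rules — are done in exact integer arithmetic
by cross-multiplying histogram counts with class sizes
(c1[m]·n2 vs. c2[m]·n1). Floats appear only in the final reported Δ, as a
single division of exact integers. Consequences: searches and predictions
are bit-reproducible, ties are genuine ties rather than rounding
artifacts, and the "equal (or zero) probability" trigger for the
prediction fallback needs no tolerance.

## Prediction and the inversion-distance fallback

A test sample is ranked **within the classifier's features only**;
restricting a ranking to a subset preserves relative order, so this equals
the full-matrix ranking wherever values are untied, and it lets a deployed
classifier run on measurements of its N features alone. The class with
the higher permutation probability at the sample's index wins (depth 0).
On exact equality, probability mass is summed over the shell of
permutations at inversion distance d = 1 (the N−1 adjacent
transpositions), then d = 2, … up to the diameter N(N−1)/2. Shells are
exact-distance sets computed by breadth-first search over single adjacent
swaps, so they are disjoint and partition the permutation set — composing
d swaps naively would over-count. If every shell ties, which happens iff
the class distributions are identical, the sample is labelled UNRESOLVED
and always scored as an error; in confusion tables it is tallied against
the true class (FN if the truth is the positive class, FP otherwise), so
counts still sum to the number of scored samples.

## Feature selection and dynamic N

Each candidate size N draws its own feature pool: the k features with the
smallest two-sided Wilcoxon rank-sum p-values (normal approximation with
midranks, tie-corrected variance, and 0.5 continuity correction; verified
against scipy's asymptotic Mann-Whitney U in the tests). Ties on p break
by larger |z|, then input order. The default budgets k = 16, 10, 9 for
N = 2, 3, 4 equalise the combination space: C(16,2) = 120, C(10,3) = 120,
C(9,4) = 126, so differences between sizes reflect the permutation space,
not the number of candidate tuples.

Dynamic N fits the best tuple for every candidate size on the training
portion, computes apparent (resubstitution) accuracy, and keeps the size
with the highest apparent accuracy, ties to the smallest N. Inside
cross-validation, both the Wilcoxon pools and the N choice are recomputed
from each fold's training samples only; a test recomputes fold fits from
the recorded training portions to audit this.

Cross-validation is stratified by default (several realistic endpoints are
heavily imbalanced, and unstratified 5-fold splits can produce
single-class training folds); `stratify=False` / `--no-stratify` disables
it. One user seed drives a `SeedSequence`-derived per-repeat seed stream,
so any repeat count is reproducible from a single integer.

## Evaluation

MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with any zero
factor in the denominator replaced by 1 — the numerator is then provably
zero, so the rule yields MCC = 0. The positive class defaults to the first
label encountered (overridable); MCC magnitude is unaffected by the
convention. ΔMCC = |cross-validation MCC − validation-set MCC| measures
overfitting. UNRESOLVED predictions count as errors in both accuracy and
MCC.

## Synthetic data

The generator plants a known tuple (the first `n_planted` feature rows)
in an i.i.d. noise background (standard log-normal by default, mimicking
the right-skewed positive scale of expression intensities). Per sample,
with probability `fidelity` the planted features take values at interior
quantiles (k+1)/(N+1) of that sample's own background values, arranged so
their ordering equals one of the class's designated permutation patterns
(drawn uniformly from the pattern set); otherwise the ordering is
uniformly random. Quantile values are nudged strictly increasing so the
planted order never depends on tie-breaking. Because planted values are
quantiles of the sample's own background, the signal is purely relative —
no marginal-scale shift — which is exactly the invariance class the
classifier lives in.

Defaults state the scenario used throughout the tests: 40 samples per
class, 50 features, a planted pair, fidelity 0.9 — a mid-sized two-class
design with a strong but imperfect rank signal. Pattern defaults are the
maximally separated pair, identity (C1) vs. full reversal (C2). Passing
the even permutations for one class and the odd ones for the other
(`EVEN_3` / `ODD_3`) plants a *pure* triplet signal: each pair's ordering
agrees in 2 of 3 patterns per class (expected pair score 1/3) while the
triplet histograms are disjoint — the scenario in which dynamic N must
prefer N = 3. Pattern sets are a deliberate extension of a
single-designated-permutation design: with one fixed pattern per class,
any pair on which the two patterns disagree is itself a perfect
classifier, so a planted signal of size N > 2 could never be "pure".

What the generator does **not** emulate: probe effects, batch structure,
correlated co-expression among background genes, missing values, or
count-based noise. A green test therefore establishes correctness of the
algorithmic machinery and its statistical behaviour under the stated
idealised world, not performance on any real platform.

The negative control (`null_generate`) emits pure noise with labels
assigned by position, independent of every value. The acceptance check
averages cross-validated MCC over 5 independent null datasets × 4 repeats
(20 repeat-level MCCs): averaging across datasets, not only across
repeats of one dataset, avoids mistaking one dataset's spurious structure
for bias in the method.

## Numerical and capacity choices

- `MAX_N = 8` bounds permutation size (8! = 40 320 histogram bins);
  experiments of interest use N ≤ 4 and search cost grows as O(N·M^N·N!).
- `search_top_classifier` refuses searches beyond 10^8 elementary
  operations (combinations × N!) unless `allow_large=True`.
- Rank ties are broken by feature input order (first-listed feature takes
  the lower rank), making every rank column a strict permutation;
  continuous expression data rarely tie, and determinism matters more
  than any particular tie convention.
- Missing/non-finite values are rejected, never imputed: within-sample
  ranks are undefined under missingness. An optional feature keep-list
  (`--keep-features`) stands in for platform-level present/marginal call
  filtering, which requires raw probe data and is out of scope.

## Known limitations

- Two classes only; no multi-class or survival endpoints.
- Exhaustive search only — no heuristic or GPU acceleration; budgets keep
  the combination space small by design.
- The k-TSP variant (votes over multiple disjoint pairs) is not
  implemented.
- Apparent accuracy is a weak model-selection signal on small samples:
  larger N can reach Δ = 1 by memorising the training fold (see the
  README's worked example). Dynamic N contains, but does not eliminate,
  this bias; cross-validated metrics are the honest estimates.
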