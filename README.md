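# tsn-classifier

Rank-based two-class classification of expression profiles with the
top-scoring 'N' (TSN) family of relative-expression classifiers, which
generalises the top-scoring pair (TSP) and top-scoring triplet (TST) to
feature tuples of any small size N.

## Who this is for

Researchers classifying two phenotypes (tumor vs. normal, responder vs.
non-responder, ...) from expression data — microarray, bulk or single-cell
RNA-seq, or lower-plex technologies such as miRNA or secretome panels —
who want classifiers that:

- use only the **within-sample ordering** of a handful of features, so they
  are invariant to any rank-preserving normalisation (quantile
  normalisation included) and portable across platforms and studies;
- are small enough to read off as a biological hypothesis ("these four
  genes swap rank order between classes");
- resist overfitting by construction, because almost nothing is tuned.

## The model

Given two classes C1, C2 and an N-tuple of features X, each sample's
ordering of X is one of the N! permutations. The Lehmer code maps every
permutation bijectively to an integer in [0, N!−1] via its factoradic digit
vector (digit i counts smaller elements to the right of position i).
Accumulating the indices per class gives two histograms; normalised, these
are the class-conditional permutation probability distributions. The TSN
score of X is

    Δ_X = ½ · Σ_{m=1..N!} | Pr(σ_m | C1) − Pr(σ_m | C2) |,

maximised exhaustively over candidate tuples. Δ_X = 1 iff the two classes
never share a permutation. For N = 2 this is exactly the TSP score
|Pr(x_i < x_j | C1) − Pr(x_i < x_j | C2)|; for N = 3, the TST score. Ties
in Δ are broken by the secondary score γ_X = Σ_samples |R(X_N) − R(X_1)|,
the rank distance between the first and last tuple features.

Prediction assigns the class with the higher probability at the sample's
permutation index. If the two probabilities are exactly equal (or both
zero), a maximum-likelihood fallback compares probability mass summed over
all permutations at inversion distance 1 (adjacent transpositions), then
distance 2, and so on; a sample is UNRESOLVED — always counted as an error
— only when both distributions are identical.

**Dynamic N** selects the classifier size inside every cross-validation
training fold: each candidate N gets its own feature pool (the most
differentially expressed genes by Wilcoxon rank-sum test; budgets 16/10/9
features for N = 2/3/4 equalise the combination space at ~120), the best
tuple per N is refitted, and the N with the highest apparent
(resubstitution) accuracy wins, ties going to the smallest N. Performance
is reported as accuracy and the Matthews correlation coefficient (MCC),
with the convention that a zero marginal in the MCC denominator yields
MCC = 0.

## Worked example

Simulate a 40-feature, 25+25-sample dataset whose first two features swap
rank order between classes in 90% of samples, then fit, cross-validate,
and predict:

```bash
tsn simulate --n1 25 --n2 25 --features 40 --planted-size 2 --fidelity 0.9 \
    --seed 7 --out-matrix expr.tsv --out-labels labels.tsv --out-truth truth.json
tsn fit      --matrix expr.tsv --labels labels.tsv --dynamic-n --seed 7 --out model.json
tsn crossval --matrix expr.tsv --labels labels.tsv --dynamic-n \
    --folds 5 --repeats 10 --seed 7 --out cv.json
tsn predict  --model model.json --matrix expr.tsv --out preds.tsv
tsn evaluate --predictions preds.tsv --labels labels.tsv
```

which logs

```
fit: chose N=4 features=('g0001', 'g0002', 'g0004', 'g0025') delta=1 gamma=520
crossval: mean accuracy=0.8940 mean MCC=0.7917
MCC	1.000000
```

Read: on the full training set, resubstitution prefers N = 4 — a tuple
containing the planted pair g0001/g0002 plus two noise features happens to
separate all 50 training samples (Δ = 1), a textbook illustration of why
apparent accuracy must not be trusted. The cross-validated mean accuracy
of 0.894 matches the planted signal fidelity of 0.9, and the final
`MCC = 1.0` line is resubstitution of the saved model on its own training
set. Per-fold selections, chosen N values, and predictions are in
`cv.json` (add `--table folds.tsv` for a flat table).

The same pipeline is available as a library: `tsn.generate`,
`tsn.rank_transform`, `tsn.search_top_classifier`, `tsn.predict`,
`tsn.cross_validate`, `tsn.mcc`, etc. See `docs/methods.md` for the full
model description and design choices.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the package's own codec, the extreme decimal indices of
the single-inversion neighbor set of the size-4 permutation with decimal
index 16: index 16 is decoded through the Lehmer code, each adjacent
transposition is applied and re-encoded, and the maximum and minimum of
the resulting set are written to the JSON output.
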