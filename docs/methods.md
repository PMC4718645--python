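# Methods

## Score definition and estimation

The average information content (AIC) of a bit set X against targets
1…K is the mean over targets of MI(X; Yᵢ)/SE(Yᵢ), where the mutual
information treats the selected columns jointly as one discrete variable
over their observed bit patterns. All probabilities are plug-in
maximum-likelihood estimates (counts over totals, no pseudocounts) with
base-2 logarithms and the 0·log 0 := 0 convention; pseudocounts would break
the exact worked-example values and the exact invariance under duplicated
bits, which are defining properties of the score.

Each per-target factor — including the pattern marginal P(x) — is estimated
on that target's own compound set. This is what allows K targets with
disjoint ligand sets to be scored together: a pooled cross-target marginal
would require every compound to be labeled for every target, which defeats
the purpose of the average. The per-target choice is a genuine modeling
decision (the pattern distribution is in principle target-independent), but
it is the only one computable from separately assembled datasets.

Patterns are represented sparsely: the selected columns of each compound
are packed into one integer code (bit-packing up to 62 columns, unique-row
indexing beyond), and only observed patterns enter the sum — unobserved
patterns have zero empirical probability and contribute nothing. This keeps
every evaluation O(rows) regardless of 2^N. Negative MI from floating-point
cancellation is clamped to 0, and normalized scores are clamped at 1.

Degenerate targets (constant labels, SE = 0) raise an error rather than
being dropped: the normalization is undefined and silent exclusion would
bias the average. Callers can exclude such targets explicitly.

## Greedy selection

AIC-Max starts from the empty set and, for a fixed number of steps N, adds
the candidate bit whose union with the current selection maximizes AIC.
Score ties (within 1e-12, which also absorbs float jitter) break to the
lowest index in feature-universe order, making runs deterministic. There is
no plateau-based early stop: users pick fixed selection sizes (e.g. 25, 50,
100) and read the information curve instead.

With subsampling enabled (default n = 10), each step conditions candidate
scores on one uniformly drawn subset of at most n already-selected bits.
The subset is drawn once per iteration and shared by all candidates of that
iteration, and the candidate is appended to it; per-candidate redraws would
compare candidates against different contexts and cost n-fold more draws.
This choice affects only the stochastic search path, not exact-mode
results. The per-step trace always records the *exact* AIC of the full
selected prefix, so information curves are comparable across subsample
settings. The RNG is a single seeded generator owned by the selection call;
no global state is touched.

Because the score is evaluated jointly, a candidate that is an exact copy
or negation of a selected bit has exactly zero gain and loses to any
candidate with positive gain — the mechanism that makes hybridizing
overlapping fingerprint families safe.

`exhaustive_best_subset` enumerates all C(p, size) subsets (guarded at 10⁶)
and is the ground-truth oracle: greedy results are tested never to exceed
it at equal size.

## Evaluation protocol

`evaluate_reduced_representation` runs k-fold cross-validation (default
k = 10). Each target's compounds are partitioned independently — compound
sets differ between targets — and fold f's training data is every target's
out-of-fold subset. Bit selection sees only the pooled training subsets;
classifiers are then trained per target on the selected columns and scored
on the held-out fold by the Matthews correlation coefficient,

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC := 0 when any marginal is empty (the standard convention; it is
also what a constant majority-class predictor earns on imbalanced data).
`information_score_cv` scores the held-out normalized MI of the selected
bits instead, using plug-in estimates on test compounds only.

Folds are stratified by default: on 9:1 imbalanced data, plain random
partitioning at small n can produce folds without actives, on which neither
selection nor MCC is defined. A `stratified=False` flag restores plain
partitioning. Training folds with constant labels raise an error naming the
fold and target.

The classifier is pluggable (any fit/predict object on binary matrices);
the default is a 100-tree scikit-learn random forest, the field's customary
baseline for activity prediction. Classifier internals are deliberately out
of scope.

## Synthetic data generator

`generate_multitarget_data` emulates the structure of screening datasets
without any chemistry. Per target: `n_actives` compounds satisfying a
boolean activity rule and `round(inactive_ratio × n_actives)` compounds
violating it (default ratio 9.0, the customary putative-inactive padding),
then optional independent label flips at rate `label_noise`. Rules are ANDs
over planted "informative" bits; the default assignment gives target i the
pair (2i, 2i+1) modulo the informative-bit count, so a handful of bits is
jointly needed and the rules collectively cover all planted bits.
Informative bits are Bernoulli(`bit_prevalence`, default 0.5) among actives
and Bernoulli(`inactive_prevalence_factor × bit_prevalence`, default factor
0.5) among label-0 compounds — decoys drawn from a vendor library are
structurally distinct from the active chemotype, which is also why single
planted bits already carry marginal signal. Rule-conditioned rows are drawn
by rejection sampling with a bounded number of rounds; specs whose rule
essentially never produces a required class raise an error rather than
spinning. "Redundant" bits are exact copies (even redundant index) or
negations (odd index) of informative bits, cycling over them; "noise" bits
are independent Bernoulli(`bit_prevalence`). The universe is ordered
informative, redundant, noise. Everything is deterministic given the seed,
and a ground-truth manifest names every bit's role and each target's rule.

What the generator does *not* emulate: real substructure correlations
between bits, potency values behind the binary labels, class-dependent bit
correlation structure, and the scale of real campaigns (thousands of
compounds × 1434 bits). Passing recovery tests therefore show that the
method finds planted joint structure under imbalance, redundancy and label
noise — not that any particular empirical screening performance is
reproduced, which would require the original bioactivity databases and
fingerprint software.

## Problem sizes used by the test suite

The packaged worked examples are exact 8-compound tables. Randomized oracle
checks use ≤ 10 features and ≤ 50 compounds so a dense 2^N enumerator stays
independent and fast. Recovery experiments use 3 targets × 2000 compounds ×
100 bits over 20 seeds, and the CV harness checks use one target ×
500 compounds with 10-fold CV and 10 label permutations — sizes chosen so
the full suite completes in well under a minute of compute per experiment
while keeping the estimators in their stable regime.

## Known limitations

* Plug-in MI is biased upward on small samples; with many selected bits and
  few compounds, held-out (cross-validated) scores are the trustworthy
  ones, which is why the evaluation module exists.
* Greedy forward selection carries no optimality guarantee (normalized MI
  is not submodular in general); the exhaustive oracle bounds it only on
  small instances.
* The subsample heuristic makes steps beyond the subsample size stochastic;
  fix the seed (recorded in every report sidecar) for reproducibility.
* Binary labels only: multi-class or continuous potency modeling is out of
  scope, as is computing fingerprints from structures — users bring bit
  matrices.
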