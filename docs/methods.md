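# Methods

## The selection procedure

`pclfsx` addresses binary classification with `n` continuous features and an
often imbalanced label (minority coded 1, always the F1-positive class). The
procedure has three stages.

**Ranking.** Features are ordered by `score_k = |L1_k| + |L2_k|`, where `L1`
and `L2` are the first two principal axes (unit-norm eigenvectors) of the
training matrix after column z-scoring. Using the correlation matrix rather
than the covariance matrix makes the ranking invariant to per-feature scale,
which matters because real datasets mix units; the raw-covariance mode is kept
behind `standardize=False`. Exactly two components are used by default (the
component count is a knob, but the method is defined on two). Eigenvector sign
indeterminacy is irrelevant because absolute values are taken. Ranking ties
are broken toward the lower column index; scores are rounded at 1e-10 before
ordering so that exactly duplicated columns actually tie instead of being
ordered by eigensolver float noise. PCA is computed on the training partition
only (after SMOTE when SMOTE is on) — never on test rows.

**Grid and maximum.** For `i = 1..n` a fresh classifier is fitted on the first
`i` ranked features and scored with minority-class F1 on held-out data, giving
the grid `g`. `n_pclfs` is the smallest `i` attaining `max(g)` (ties go to the
smaller subset). Grid indices are 1-based subset sizes in every public value,
matching the `g_j` notation; arrays are 0-based internally and the mapping is
asserted in tests.

**Gradient-threshold reduction.** Candidates are the strict local maxima
`g_j > max(g_{j−1}, g_{j+1})` with `j < n_pclfs`. At `j = 1` the missing left
neighbour is treated as −∞, so an initial peak can qualify — excluding it
would forbid exactly the very small subsets the method exists to find. The
neighbour of `j = n_pclfs − 1` is the maximum itself, so that point can never
qualify. Ties with a neighbour (plateaus) disqualify a point: the rule is a
strict inequality, and plateaus silently fail. Each candidate is joined to the
maximum point and its gradient `(g_{n_pclfs} − g_j)/(n_pclfs − j)` — the F1
loss per feature removed — is compared *strictly* against `t = T/n`. `T` is
user-defined (default 0.05); `n` is the **total** feature count of the
dataset, not `n_pclfs`, so that the threshold stays comparable across datasets
of different widths (0.05/44 ≈ 0.0011 for a 44-feature dataset, 0.05/30 ≈
0.0017 for the 30-feature simulations). The smallest qualifying candidate
becomes `n_proposed`; with no candidate (including `n_pclfs = 1`) the PCLFS
result is returned unchanged (`fallback=True`). Because every accepted
gradient is below `t` and `n_pclfs − n_proposed ≤ n`, the realised loss obeys
`g_{n_pclfs} − g_{n_proposed} ≤ t·(n_pclfs − n_proposed) ≤ T`; this bound is
asserted on every composed run.

**Final subset.** The classifier refitted on the `n_pclfs`-feature training
data supplies importances (|coefficients| for linear models, impurity-based
importances for trees and ensembles), and the subset keeps the `n_proposed`
highest-importance features among the active ones, ties broken by ranking
position. This importance-based re-selection — rather than truncating the
ranking prefix at `n_proposed` — is the reading we implement of "use the
feature importance scores"; prefix truncation is available by taking
`ranking_.order[:n_proposed]` directly.

## Evaluation protocol

Data are split 75/25 stratified by class. SMOTE, when used, is applied to the
training partition only — the test partition is never resampled, otherwise
the reported F1 would be contaminated by synthetic rows. SMOTE balances the
classes exactly: each synthetic row is `x + u·(x_nn − x)` for a minority row
`x`, one of its `k = 5` nearest minority neighbours (Euclidean) and
`u ~ Uniform(0,1)`; original rows are preserved verbatim, and `k` is reduced
with a logged warning when the minority class has fewer than `k + 1` members.

The RFE baseline is standard recursive elimination (step 1) with the subset
size chosen by 5-fold stratified cross-validated F1, via scikit-learn's
`RFECV`; per-size CV scores are logged.

## The synthetic-data generator

Each dataset has one Gaussian cluster per class. Class counts are
deterministic (majority `= round(l·w_major)`, minority the remainder). The
`n_informative` informative columns are built from latent class-dependent
factors: latent axis `j` has variance drawn from Uniform(0.5, 2) and class
centroids at `±class_sep/√k`, so the total centroid separation is
`2·class_sep` independent of `k`; the latent block is then mixed by a random
rotation to form the informative columns. The remaining columns are standard
normal and independent of the label. Columns are randomly permuted (the
informative positions are recorded in `informative_mask`), and an optional
`flip_y` fraction of labels can be flipped (default 0).

Two design points matter and were genuinely open:

- *Why normalise the separation over the informative subspace?* If each
  informative axis contributed a fixed separation, ten informative features at
  `class_sep = 2` would separate the centroids by ~12σ: a single feature would
  classify near-perfectly, the grid would saturate at two or three features,
  and the characteristic selection curve — F1 leaping upward until the
  informative features are captured, then flattening — could not occur. With
  the total separation fixed at `2·class_sep`, individual features are weakly
  informative, the joint set is strong, and the curve has the intended shape
  (at `class_sep = 2` the plateau sits near the Φ(−2) ≈ 2.3% oracle error).
- *Why heterogeneous latent variances and a rotation?* With a spherical
  within-class informative block, every within-class principal direction has
  variance 1, so the second principal component is a pure noise direction and
  the |L1|+|L2| ranking mixes noise features into the top ranks. Real
  informative blocks (and the standard library generators) are correlated and
  uneven; the rotation of unequal-variance latents reproduces that, placing
  both leading PCs in the informative subspace.

What the generator does **not** emulate: redundant (exact linear-combination)
or repeated features, categorical features, multiclass labels, non-Gaussian
marginals, and heavy-tailed noise. Passing simulation tests therefore show
recovery behaviour under a favourable, well-specified signal model; on real
data the ranking can be degraded by strong uninformative variance directions
(e.g. batch structure), which PCA cannot distinguish from signal.

## Simulation harness

A scenario fixes sample size, feature count, a sweep over `n_informative`,
the imbalance rate (50:50, 70:30, 90:10), the classifier (logistic, linear
SVM, decision tree, random forest, optional gradient boosting), SMOTE on/off,
`T`, and a replicate count. Per replicate: generate → 75/25 stratified split →
optional SMOTE on the training part → run RFE, PCLFS and PCLFS-ext on the
shared data → record F1, error rate, subset size, TPR_fs (fraction of truly
informative features recovered) and the correct percentage, defined as the
per-feature accuracy of the selection viewed as a binary decision,
`100·(TP + TN)/n` (the alternative readings of "correct percentage" can be
swapped in; the output column is labelled). Replicate seeds are
`base_seed + replicate_index`, so partial reruns reproduce; degenerate
replicates (a class missing from a split) are skipped with a logged warning
and excluded from denominators, never silently zero-filled.

Default problem sizes: the packaged experiments and the acceptance script use
1000 samples, 30 features, 10 informative, 20 replicates — large enough that
the recovery metrics stabilise (the ext-selection TPR_fs varies by about
±0.02 across independent 20-replicate batches) while a full run stays in the
tens of seconds on one core.

## Numerical conventions and edge cases

- F1 uses the 0-when-TP=0 convention; error rate is `100·(1 − accuracy)`.
- Constant columns standardise by dividing by 1 instead of 0, with a warning.
- A single-feature dataset gets loading vectors `(1)` and `(0)` and a
  one-point grid; the extension then always falls back.
- `T = 0` makes the strict gradient inequality unsatisfiable, so PCLFS-ext
  degenerates to PCLFS exactly.
- All randomness (generation, splits, SMOTE, classifier fits) flows from
  explicit integer seeds; identical inputs give bit-identical outputs.

## Known limitations

- The ranking is purely unsupervised (PCA of the feature block); features that
  are informative but low-variance after standardisation — e.g. informative
  only through interactions — rank poorly.
- The grid refits the classifier `n` times per run; for very wide data the
  cost is linear in `n` times the classifier's fit cost.
- The threshold `t = T/n` spreads the tolerance over the *total* feature
  count; for extremely wide datasets this makes `t` very small and the
  fallback correspondingly common. That is the intended conservative
  behaviour, but users of wide data may prefer a larger `T`.
- `correct_pct` and `TPR_fs` require ground-truth informative features and so
  are only available on simulated data.
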