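# Methods

## Model and procedure

`evoselect` is a wrapper-style optimizer: a population of candidate
solutions ("chromosomes") is evolved, where each chromosome is a pair
(hyperparameter vector for the nested learner, feature subset). The
fitness of a candidate is a cross-validated Bayes Information Criterion,
so selection pressure simultaneously rewards predictive fit and
penalizes model size. The procedure assumes a fixed tabular dataset with
a single continuous or binary target, independent rows, and features on
comparable (prepared) scales.

### Search space

Hyperparameters are sampled uniformly on their stated ranges — uniform
over integers for integer-valued ones (tree depth) — and the feature
subset size is uniform on [1, 50] (clamped to the pool). Uniform rather
than log-uniform sampling is deliberate: the ranges are the search
contract and the simplest distribution over them introduces no scale
prior. Duplicates in a population are permitted; nothing deduplicates
random draws. The library-default value attached to each hyperparameter
is used only by the no-optimization baseline and may legitimately sit
outside the evolution range (the boosted-tree L1 penalty defaults to 0
while its evolution range is 0.1–0.9; both are kept as configured, since
the baseline describes the library default, not the search).

### Fitness

Cross-validation adapts to the candidate: k = ⌈n_samples/n_features⌉,
clamped below at 2 and above at n_samples, stratified for
classification. This gives near-leave-one-out CV to small models; the
optional `k_cap` (unset by default; 4–10 in this repository's tests)
bounds the cost at desk scale. If a class cannot appear in every
training fold, k is reduced one step at a time down to 2.

Fitness is computed on pooled out-of-fold predictions — exactly the
predictions the CV produced, never a refit —

* regression: `n·ln(max(SSE/n, 1e−12)) + p·ln(n)` (Gaussian residuals),
* classification: `−2·Σ ln p̂ᵢ(yᵢ) + p·ln(n)` with probabilities clipped
  to [1e−12, 1−1e−12] (Bernoulli likelihood),

with `p = |features| + 1` (an intercept; fixed architecture settings are
not free parameters of the *selection* problem and are not counted).
The clipping floor keeps fitness finite for degenerate fits; a failed
inner fit is recorded as a `+inf` sentinel rather than raised, so a
pathological gene combination cannot abort a run. Under these
conventions classification BIC is strictly positive; no sign flip or
rescaling is applied to it anywhere.

### Generation step

With base population n (default 100), standard phase:
0.2n recombined + 0.2n mutated + 0.6n random = n, the worst 0.4n
discarded. Recombination pairs the ranked parents disjointly
(1&2, 3&4, …), averages every hyperparameter arithmetically (integers
round half-up, then clamp) and passes the higher-ranked parent's feature
set to the child — so all 0.4n children carry top-ranked feature sets
forward. Mutation shifts *every* hyperparameter by its fixed step with
an independent random sign, clamped to range, keeping the feature set.
Ranking is a stable sort on (fitness, fewer features, insertion order),
which makes tie-handling reproducible.

Plateau detection: the best fitness of each generation is recorded; the
run stops when the best over the last `window` generations (default 20)
improves on the best before that window by less than `tol` (default
1e−4, relative). With fewer generations than the window the answer is
always "not yet". A run that exhausts `max_generations` (default 500)
is returned flagged unconverged, never raised. The number of
generations to plateau is data- and seed-dependent by construction;
no fixed count is assumed anywhere.

### Warm start

After the initial plateau, per-feature importances are aggregated as the
mean absolute importance over the archived best models containing the
feature (features never selected score 0, rank last; ties break by
feature id). The elbow is located on the upper envelope of best
performance (accuracy or R²) per feature count, taken over **every model
evaluated during the run** — the best-distinct archive alone is not used
for the curve because, once a dominant feature set saturates breeding,
the archive collapses onto one or two feature counts and the curve
degenerates. The elbow is the envelope point with the largest
perpendicular distance to the chord joining its endpoints (computed on
axes normalized to [0,1]; the argmax is invariant under affine rescaling
of either axis, so this equals the raw-unit chord criterion); exactly
affine envelopes return the smallest count.

The importance of the elbow-th ranked feature is the base threshold; the
schedule adds 0–4 population standard deviations of the nonzero
aggregated importances. Each of the five thresholds constrains the pool
to features at or above it (a nested chain of pools), and an independent
fresh-start evolution runs at half population (0.5n, with 0.2n
recombined and 0.1n mutated per generation) on each pool; the stage
whose best model attains the lowest fitness wins. Independent restarts
were chosen over one continued run with tightening pools because they
keep the five stages exchangeable and individually reproducible.

### Inner learners

All learners sit behind one adapter contract (scikit-learn estimators
parameterized directly by the genes, exposing importances after fit):

* **Elastic net** (`linear`): genes are the L1 and L2 penalty weights in
  [0,1] applied directly. The fitting routine's (strength, mixing)
  parameterization is reached through the bijection `alpha = l1 + l2`,
  `l1_ratio = l1/(l1+l2)` (inverse `l1 = alpha·l1_ratio`,
  `l2 = alpha·(1−l1_ratio)`), with the unpenalized model at l1 = l2 = 0.
  Importances are the signed coefficients, ranked by magnitude.
* **Gradient-boosted trees** (`tree`): genes are maximum depth (2–10),
  node-partition threshold gamma, and L1 penalty alpha, taken at face
  value on the library's native scales. The ensemble size is fixed at
  100 rounds (a fixed setting recorded in configuration, not a gene).
  Importances are the ensemble's gain importances.
* **Feedforward network** (`net`): genes are the Adam learning rate and
  decay rates beta1/beta2. Fixed settings: rectified-linear hidden
  units, 3 layers × 300 neurons by default (configurable; tests use
  2 × 16 with minibatches of 16 so that learning is observable within an
  early-stopping patience of 3), early stopping on the loss of an
  internal 10% validation split (stratified for classification), softmax
  output for classification. Importances are permutation importances
  (mean drop of accuracy/R² over 5 shuffles of one column, on the
  evaluation set), which keeps the network explainable in the original
  features. Fits are deterministic given a seed.

### Validation and baseline

The best 100 distinct models (archive key: sorted feature ids +
hyperparameters rounded to 12 significant digits) are refit on the full
train/test partition and scored once on the held-out validation
partition — always native data, never resampled. The single winner is
chosen by accuracy (classification) or R² (regression), ties broken by
validation BIC. The baseline repeats the experiment without
optimization: library-default hyperparameters, all features, the same
cross-validation.

## Preparation pipeline

Fixed order: split (~70/30) → missingness filter → winsorize → impute →
scale/transform → (classification) discretize + balance. Statistics are
always fitted within one partition; the two partitions never share
state.

* Missingness: features with *strictly more than* 40% missing are
  dropped; exactly 40% is kept.
* Winsorizing: clip to mean ± 3 population SDs (moments ignore missing
  cells); zero-variance features pass through. Clipping with fitted
  bounds is idempotent. Note a single outlier among n points can never
  exceed (n−1)/√n population SDs, so at very small n the bounds cannot
  engage — outlier trimming is meaningful only at realistic sample
  sizes.
* Imputation: masked multiplicative-update NMF (rank default
  min(10, features/4), tol 1e−5 relative per iteration, max 500
  iterations, min-shift to non-negativity reversed afterwards). Only
  missing cells are replaced; observed cells are untouched; the observed
  loss is non-increasing. Fully missing rows/columns are an error naming
  the offender. The imputation is transductive (`fit_transform`).
* Scaling: min-max to [0,1]; constant features map to 0.
* Transform selection: per feature, the candidates identity /
  normal-quantile / Yeo–Johnson power compete on the normality score
  |skewness| + |excess kurtosis|; lowest wins, ties to identity; needs
  ≥ 20 observed values.
* Item agglomeration: standardized items merged by Ward-linkage feature
  agglomeration to one cluster; the pooled value equals the mean of the
  standardized items.
* Targets: case iff score > cutoff (cutoffs are required configuration —
  they are dataset-specific and no universal value exists). Balancing is
  SMOTE (k = 5 neighbor interpolation to parity, k reduced to
  minority−1 below 6) followed by edited-nearest-neighbour cleaning
  (k = 3, all classes, never removing a class entirely), applied to the
  train/test partition only.

## Synthetic data

The generator emulates the statistical shape of a wide multi-instrument
battery: default 1000 × 160 continuous features, a sparse linear signal
(8 informative features, optional pairwise interactions), redundant
noisy copies (noise SD = 0.1 of the parent's, mimicking collinear
instruments), a skewed fraction of noise features (exponentiated),
MCAR missingness with per-feature rates up to a cap (≤ 0.5), and for
classification a logistic link whose intercept is tuned by bisection to
the requested case fraction within ±2%. Everything is determined by
spec + seed.

What it does **not** emulate: structured (non-random) missingness,
measurement floors/ceilings, batch effects, non-linear main effects, and
any time-course or connectivity structure. Passing recovery tests on
this generator therefore shows the optimizer finds sparse linear-ish
signal under realistic nuisance structure, not that it handles every
pathology of observational data.

An exhaustive best-subset oracle (all non-empty subsets, same BIC
convention, guard at 15 features) provides the independent reference the
evolutionary search is compared against on small pools.

## Problem sizes in tests and the acceptance script

Recovery and comparison experiments run at desk scale, chosen once:
300 samples × 30 features (3 informative) with population 20 and plateau
window 10 for recovery; 150 × 10 (2 informative) with warm start and a
150-generation cap for the oracle comparison; 430 samples split 70/30
for the evolved-vs-default comparisons (population 20/10, caps 25/10 for
the linear/tree learners). These sizes keep full runs in minutes while
leaving the contracts sharp; the composition checks run at the reference
population n = 100.

## Numerical choices and degenerate inputs

* ε = 1e−12 likelihood/variance floors (finiteness of fitness).
* Integer genes: round half-up, clamp after rounding.
* Archive rounding to 12 significant digits defines model identity.
* Population smaller than 3 still yields a queue entry (with a warning).
* Zero spread of aggregated importances collapses all five warm-start
  thresholds to one (with a warning).
* Plateau reference of exactly 0 falls back to an absolute tolerance.

## Known limitations

* Feature sets change only through inheritance and fresh random draws
  (no subset crossover), so aggressive pruning happens mainly in the
  warm-start phase; on unconstrained pools the pre-warm-start best model
  typically carries extra passenger features.
* Fitness counts only |features| + 1 parameters; hyperparameters and
  network weights are not charged, so fitness comparisons are meaningful
  within a learner, not across learners of different capacity.
* Evaluation is sequential (single process); the population loop is
  embarrassingly parallel but parallel execution is out of scope.
* The adaptive-k rule approaches leave-one-out for small subsets, which
  is expensive and high-variance; `k_cap` is the practical control.
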