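# Methods

## Model

Given `n` samples with labels in {+1, −1} (+1 always the minority /
positive class), the classifier learns a scoring function
`F(x) = Σ_m ρ_m f_m(x)` whose goal is to score every minority sample above
every majority sample. The training objective is defined on the exhaustive
set of `K = S × T` minority–majority index pairs: the 0/1 ranking loss
counts reversed pairs (a tie counts as correctly ranked), and its convex
surrogate is the squared hinge with margin `τ`

    L̃(F) = ½ Σ_k max{0, F(x̄_k) − F(x_k) + τ}²,

which is convex in the vector of sample scores (a sum of squares of
pointwise maxima of affine functions). A strictly positive `τ` is required:
at `τ = 0` the constant scorer is a global minimizer and nothing is learned.

### Gradients

The partial derivative of `L̃` with respect to a single sample's score sums
the contributions of every pair containing that sample. A pair contributes
only while it is *active*, i.e. while `F(x_k) < F(x̄_k) + τ` (strict; at the
boundary the hinge term and its derivative both vanish). The per-sample
negative gradient vector is the quantity the base learners are fitted to:
fitting one tree to the aggregated per-sample gradients is mathematically
identical to descending the pairwise objective, but costs `O(n)` tree rows
instead of `O(K)` duplicated pair rows. A central-finite-difference oracle
in the test suite certifies the aggregation against the loss itself at
1e−6 absolute tolerance.

### Boosting loop

Starting from `F ≡ 0` (so the initial loss is exactly `K·τ²/2`), round `m`:

1. compute the per-sample negative gradient at the current scores;
2. fit a depth-limited regression tree `h_m` to it;
3. choose `ρ_m = argmin_{ρ ∈ [0, ρ_max]} L̃(F + ρ·h_m)` exactly — the
   restriction of `L̃` to the ray is convex piecewise quadratic, so its
   derivative is nondecreasing and bisection brackets the minimizer to
   1e−8; when the derivative is zero over a flat stretch (all hinges
   released) the *smallest* minimizer is returned, keeping score scales
   moderate;
4. update `F ← F + ν·ρ_m·h_m` and append the new loss to the trace.

Stopping: a hard cap of `max_iter` rounds, or relative loss decrease below
`rel_tol`, or the loss reaching exactly zero, or a round in which no step
can decrease the loss (`ρ = 0`). With exact line search and `ν = 1` the
loss trace is non-increasing by construction, and this is asserted on
every fit.

After the final round the cut-off is `C = (mean of minority scores + mean
of majority scores) / 2`, computed on the training data only; prediction is
minority iff `F(x) ≥ C`, ties going to the minority class. A zero-round
model therefore scores everything 0 and predicts all-minority — a
documented degenerate behavior, conservative in the direction this method
cares about.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `max_iter` | 100 | boosting rounds cap; training on all reference fixtures plateaus well inside it |
| `tau` | 1.0 | ranking margin (score units); tree outputs adapt to any fixed positive value, so it only sets the score scale |
| `tree_max_depth` | 3 | shallow trees keep base learners weak and fitting `O(n·depth)` |
| `tree_min_leaf` | 5 | guards leaf estimates against single-point noise |
| `shrinkage` (ν) | 1.0 | optional damping in (0, 1]; 1.0 keeps the exact-line-search monotonicity sharp |
| `rel_tol` | 1e−6 | relative per-round loss decrease below which training stops |
| `rho_max` | 1e3 | line-search bracket; never binding on the reference fixtures |
| `seed` | 0 | passed to the tree learner; the whole fit is deterministic given it |

## Data handling

CSV (header row, RFC-4180 style) and UCI-dialect ARFF (via
`scipy.io.arff`) are read into a dense numeric matrix. Nominal attributes
are one-hot encoded over their observed levels; `?` is the missing-value
token. Missing numerics take the column median, missing nominals the
modal level; imputation never drops rows, so published instance counts are
preserved. The imputation value and level set of every attribute are
recorded in the model file, and prediction re-applies exactly the
training-time encoding (unseen levels encode as an all-zero block). The
caller must name the positive label explicitly — inferring it from rarity
is refused because it is ambiguous on near-balanced subsets.

## Synthetic generator

The generator emulates the structure the method targets: `n_pos` minority
rows and `n_neg` majority rows with unit-variance isotropic Gaussian
numeric features whose class means differ by `separation` (in within-class
standard deviations) along the first axis, optional 3-level nominal
attributes with class-dependent level frequencies, and optional
missing-at-random cells at `missing_rate`. Reference fixtures used across
the tests and the acceptance script:

- **separable** — 20/80, dim 2, separation 6, seed 7 (verified linearly
  separable by a perceptron-convergence oracle);
- **moderate** — 30/170, dim 5, separation 2, two nominal attributes, 5%
  missing cells, seed 4;
- **null** — 20/80, dim 2, separation 0, seed 1 (no class signal).

What the generator does *not* emulate: correlated or heavy-tailed
features, label noise, informative missingness, and the attribute mixes of
real clinical tables. Passing tests on these fixtures therefore show the
machinery is correct (the optimizer finds a perfect ranking when one
exists, and does not fabricate signal from noise), not that real-data
benchmark numbers will be reproduced.

## Evaluation protocol

Only the minority class is scored: TPR = TP/(TP+FN), PPV = TP/(TP+FP),
and F = (1+β²)·TPR·PPV/(β²·TPR+PPV) with β = 1 by default.
Cross-validation uses **stratified** k-fold splits (default k = 10) formed
once from the seed — plain random splitting can strand a fold without
minority members on small datasets, which would make its TPR undefined.
Per metric we report the fold mean, the symmetric interval
mean ± t₀.₉₇₅,ₖ₋₁·sd/√k (which may extend past [0, 1]), and two F
aggregations, labeled: the mean of per-fold F values and the F recomputed
from mean TPR and mean PPV. Both appear because they genuinely differ and
summaries in the literature are not always explicit about which is shown.

Degenerate folds: when a fold receives no positive predictions its PPV
(and F) are undefined; the undefined flag is NaN at the fold level, and
fold means substitute 0 with a logged warning rather than silently
dropping the fold. `evaluate_adapter` runs any external object with
`train(features, labels)` / `predict(features)` through the identical
protocol, so comparison classifiers can be benchmarked without
re-implementing them here.

## Numerical choices and edge cases

- Ties in the 0/1 ranking loss count as correct (the `≥` branch of the
  indicator); the margin in the surrogate exists precisely because of this.
- Pair order is deterministic (minority-major), so loss values and traces
  are reproducible bit for bit; model files are JSON and round-trip
  bit-exactly.
- Pairing is exhaustive by default; index vectors for the largest
  published-scale case (~841k pairs) are a few megabytes.
- The line-search tolerance (1e−8 on the bracket) is far below any loss
  curvature encountered; the random-probe oracle in the tests confirms
  global optimality of the returned step.
- Single-class inputs, non-finite features, dimension mismatches, and
  truncated or foreign model files all raise structured errors naming the
  offending quantity.

## Design choices made where the design was open

- **Per-sample gradient aggregation** (one tree per round) rather than two
  trees on per-pair targets: it is the exact functional gradient and
  scales with `n`, not `K`.
- **Exact line search** for `ρ` rather than a fixed step: it makes the
  monotone-loss property checkable rather than merely hoped for.
- **Stratified folds** rather than plain random folds: keeps every fold
  evaluable on imbalanced data.
- **Imputation at load time, fitted on the full table.** Encoding and
  imputation are not re-fitted inside each CV training split; with
  median/mode imputation on the data sizes involved the leakage is
  negligible, but it is a known limitation of the current pipeline.
- **t-based symmetric confidence intervals**; other constructions
  (bootstrap, Wilson) would not be symmetric, and symmetric intervals can
  legitimately extend outside [0, 1] on near-degenerate fold variances.

## Problem sizes

The test suite and the acceptance script run entirely on the reference
fixtures above (100–200 samples, up to 5100 pairs, ≤ 100 boosting rounds,
10-fold CV repeated for three fold seeds); the full suite completes in a
few seconds on one CPU.

## Known limitations

Binary classification only. No pair subsampling, stochastic boosting, or
alternative base learners beyond the train/predict adapter contract.
Scores are uncalibrated ranking scores, not probabilities. The majority
class's own error rate is deliberately not optimized: the objective cares
only about ranking minority above majority.
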