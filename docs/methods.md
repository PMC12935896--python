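# Methods

## Problem setting

Small clinical cohorts labeled with autonomic-nervous-system (ANS) states
from heart-rate-variability (HRV) features are typically severely
imbalanced: one "balanced" state dominates while clinically important states
may have fewer than ten members. Classifiers trained on such data learn the
majority class and miss the minorities. `hrvbalance` implements a hybrid
resampling method — refined SMOTE oversampling followed by refined ENN
editing — together with the four-classifier benchmark used to evaluate it,
and a synthetic cohort generator so the whole pipeline can be exercised
without access to any private clinical data.

## Refined SMOTE

All interpolation runs in z-scored feature space, z = (x − μ)/σ with μ the
column mean and σ the **population** standard deviation (divisor n). The
population form is the plain z-score definition; with the sample divisor
(n − 1) the two differ by under 1% at the cohort sizes involved, and
`fit_standardizer(ds, ddof=1)` exposes the alternative. Constant features
are rejected by name rather than silently producing infinities.

For each minority class below its target count, synthetic rows are built
from a seed sample x_i and a partner x_j drawn uniformly from the seed's
k = 3 same-class nearest neighbours (Euclidean distance; distance ties break
toward the lower row index so the neighbour sets are reproducible). Seeds
cycle round-robin over the class's rows so every original contributes
equally; the schedule is a deliberate choice where any unbiased schedule
would do. Two interpolation modes, chosen per-sample by a Bernoulli draw
with probability 0.5 of the off-line mode:

* **in-line**: x = x_i + λ(x_j − x_i), λ ~ U[−1, 1]. The negative half of
  the range extrapolates beyond x_i, widening the synthetic cloud relative
  to classic SMOTE (λ ∈ [0, 1]; available as `classic_preset()`).
* **off-line**: x lies on the circle whose diameter is the segment
  x_i–x_j, at distance d·cosθ from x_i (d = ‖x_j − x_i‖, θ ~ U[−π/2, π/2]).
  By Thales' theorem (x − x_i)·(x − x_j) = 0; θ = 0 lands exactly on x_j
  and θ = ±π/2 exactly on x_i (both coincidences are returned exactly, not
  just to rounding).

The off-line construction is stated in the plane; in p > 2 dimensions the
perpendicular within the diameter plane is not unique, so the implementation
draws an isotropic random unit vector, projects out the x_i→x_j component
and normalises (resampling in the measure-zero degenerate case). This keeps
both printed contracts — the d·cosθ distance and the endpoint coincidences —
in any dimension, and with the clockwise perpendicular it reduces exactly to
the planar closed form. Whether θ's sign means anything in ≥3 dimensions is
moot: it is absorbed by the random perpendicular.

Per-class targets default to the majority-class count. The emulated study's
count table implies some post-editing minority counts above the original
majority, so its (unpublished) targets were evidently higher; targets are
therefore fully configurable and the default is an assumption. If a partner
coincides with its seed (duplicate rows), the sample degrades to in-line
interpolation, which returns the seed itself. A class of exactly one member
cannot be oversampled and is an error; a class smaller than k + 1 clamps k
with a warning.

## Refined ENN

After oversampling, every row (original and synthetic, majority included —
this is what shrinks an oversized majority class) is voted on by its k = 3
nearest neighbours of any class. A row whose label differs from the strict
majority of its neighbours — or whose neighbours produce no strict majority,
possible with 3 votes and 7 classes; ties are conservatively treated as
disagreement — is flagged as a boundary row. Flags are computed in one pass
over the fixed dataset, not sequentially after each removal.

Classical ENN would delete all flagged rows. The refined variant retains
`round(retain_fraction · n_flagged)` of them (default 0.15, the midpoint of
the 10–20% range the method prescribes), drawn uniformly at random and, by
default, stratified per class with largest-remainder quotas so small classes
are not stripped of their entire boundary. Two guards extend the published
description: retention is stratified rather than fully uniform, and if
editing would empty a class entirely, the flagged row nearest that class's
centroid is retained with a warning.

Surviving original rows are copied back from the input verbatim after the
inverse z-transform, so the optimized dataset's original rows are
bit-identical to the input's.

## Protocols and leakage

`run_protocol` offers `paper_faithful` (resample the full dataset, split
80/20 after — the flow whose leakage the source analysis itself
acknowledges) and `leakage_safe` (split first, resample the training
partition only; the test set stays all-original). The default everywhere is
`leakage_safe`. The standardizer is fit on whatever data enters the
resampler. The test fraction maps to `ceil(n · fraction)` test rows — the
convention that reproduces a 937/235 split of 1172 rows at 20%. The split is
simple random by default with a stratified option; with 6-member classes a
plain 80/20 split frequently drops a class from train, so the benchmark
experiment uses the stratified option.

## Classifier benchmark

Hyperparameters follow the grid-search optima of the emulated study: SVM
(RBF, C = 10, γ = 1; probabilities via pairwise-coupling calibration, an
approximation needed for ROC), random forest (1000 trees, entropy, sqrt
features, no bootstrap), k-NN (k = 3, Euclidean), and a 256/128/64 ReLU
multilayer perceptron. The network is trained with scikit-learn's
`MLPClassifier`: adam, batch 32, L2 `alpha=1e-4` , early stopping on a 10%
validation slice with patience 30, adaptive learning-rate decay, at most 500
epochs. This realises the stated training strategy (early stopping +
adaptive learning rate); batch normalisation and dropout are not part of
`MLPClassifier`, so regularisation rests on L2 and early stopping — a known
deviation of this package's NN from the described architecture. Every model
standardizes features with a transform fit on its own training data.

Metrics: accuracy plus **unweighted macro** one-vs-rest precision, recall
and F1 (the averaging scheme is not named in the source; macro is the
natural choice for a test set balanced by resampling, and classes absent
from the truth are excluded from the macro). ROC is one-vs-rest per class
with trapezoidal AUC — equivalent to the midpoint-tie rank statistic — and
macro AUC is the unweighted mean over classes with both positives and
negatives. Feature importance uses permutation importance (mean macro-F1
drop over 20 seeded column shuffles) for all four models, because the
cross-model mean-rank table needs one comparable scale; the forest's
impurity importance is additionally available. Within each model, rank 1 is
the largest score with ties averaged; mean rank is the across-model mean.

## Synthetic cohorts

The generator draws class-conditional **log-normal** features: HRV spectral
powers and time-domain statistics are positive and right-skewed, and the
log-normal respects both. Seven base features (HR, SDNN, rmSSD, PNN50, VLF,
LF, HF) share a fixed correlation structure (e.g. SDNN–rmSSD 0.7,
rmSSD–PNN50 0.8, HR negatively related to vagal indices) and each ANS state
shifts the log-means directionally according to its physiology (stress: high
HR and LF, low SDNN/rmSSD/HF; dysautonomia: globally low variability; etc.).
The derived columns are then computed, not sampled: TSP = (VLF + LF + HF) ×
(1 + ε) with ε ~ N(0, 0.02), and LF/HF = LF ÷ HF exactly — so the strong
feature couplings that make naive-independence assumptions fail are present.
Default class counts are {63, 6, 9, 195, 12, 24, 12} (total 321).

The magnitude of the class shifts (2 log-SD units along each state's
direction) is the generator's separation default, chosen so the classes are
separable but overlapping: a no-resampling baseline visibly misses the
minority states (macro-F1 ≈ 0.4–0.6 depending on model) while balanced
training recovers them. An `overlap` knob shrinks separation by
1/(1 + overlap) for harder variants. What the generator does **not** emulate:
real measurement noise structure, within-subject correlation, label noise,
or any particular cohort's moments (they are unpublished). Passing tests
therefore demonstrate the machinery's correctness and the direction of the
resampling effect under controlled conditions, not clinical performance.

`planted_boundary_cohort` builds the editing module's ground-truth fixture:
two unit-variance Gaussian clusters with centers 10 units apart plus a few
points drawn from one cluster's distribution but labeled as the other.

## Effect-direction experiment

`hrvbalance.experiments.resampling_effect_experiment` compares three
training conditions on freshly generated cohorts under the leakage-safe
protocol: no resampling, classic SMOTE alone (λ ∈ [0, 1], in-line only, no
editing — the traditional comparator), and refined SMOTE-ENN with defaults.
All three conditions share each run's cohort and split, so comparisons are
paired. Summary statistics are per-model medians over 10 runs and the
median over runs of the four-model mean. Ten runs of 321-row cohorts keep
the full experiment to a few minutes on one CPU; the qualitative ordering
(refined ≥ none for every model, refined ≥ classic on the four-model mean)
is stable across master seeds, though the refined-vs-classic margin on
these synthetic cohorts is small — a few hundredths of macro-F1 — rather
than the large gap reported on the original clinical data.

## Numerical notes

* CSV round-trips are exact: floats are written at 17 significant digits and
  parsed with pandas' `round_trip` parser.
* Orthogonality/unit-norm preconditions of the off-line construction are
  enforced at 1e−9; the degenerate perpendicular resample threshold is
  1e−12.
* `round(retain_fraction · n_flagged)` uses round-half-up, so 0.15 · 20 → 3.
* All stochastic stages take explicit integer seeds and are reproducible
  bit-for-bit; forests and k-NN run single-threaded for determinism.
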