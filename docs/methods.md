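# Methods

## Problem setting

Binary grading of gliomas (low- vs high-grade) from expert-labeled MRI
segmentations, in the small-sample regime (~275 subjects) where single
classifiers overfit. The package implements the full chain: descriptor
features from label volumes, the EL-APMC ensemble, and a benchmarking
harness, with synthetic generators making every stage testable without
external data.

## Feature extraction

A segmentation volume assigns each voxel one of five roles (background,
necrosis, edema, non-enhancing tumor, enhancing tumor; default integer
coding 0–4 in that order, the BRATS2015 convention, overridable). For
descriptor D with total voxel count c_D and z the number of slices (third
axis, configurable) containing at least one tumor voxel of *any* label:

* mean presence: `D_M = c_D / z` (voxels per tumor-bearing slice);
* ratio: `D_R = D_M / (tC_M + tnC_M + Edm_M + Nec_M)`.

Two deliberate choices where alternatives were conceivable:

* **Shared slice denominator.** z counts slices with any tumor label, not
  per-descriptor slices. A per-descriptor z would give the four means
  incommensurable scales and make the ratios fail to sum to 1.
* **Common ratio denominator.** All four ratios share the sum of the four
  means, so they form a composition on the simplex (sum = 1 within 1e-9,
  enforced by a validation invariant).

A volume without tumor voxels has z = 0 and undefined features; it is
rejected as a domain error rather than mapped to zeros, since a zero
vector would silently impersonate a valid composition.

## The ensemble

* **Bagging without replacement.** Each of the N bootstrap subsets is a
  seeded permutation of the training indices cut into an InBag of
  ⌊n·f⌋ rows (f = 0.5 default) and an OutBag of ⌊n·(1−f)⌋ rows — disjoint
  within a subset; duplicates occur only across subsets. Odd leftover rows
  are dropped from that subset. A single-class InBag is redrawn up to 20
  times before erroring.
* **Random subspace.** Each base learner sees a uniformly random feature
  subset of size round(√NoF) (half-up rounding, clamped to [1, NoF]); with
  the 8 descriptor features that is 3.
* **Base learner.** A two-class linear discriminant (scikit-learn LDA,
  `lsqr` solver with Ledoit–Wolf shrinkage so degenerate bags with
  near-constant columns stay fittable). Its output k_i is the logistic of
  the discriminant function — the positive-class posterior — clipped to
  [1e-6, 1 − 1e-6] so negative-exponent means are defined.
* **Per-learner weights.** Each learner's OutBag accuracy is recorded. By
  default fusion is unweighted; `use_weights=True` switches to a weighted
  power mean with weights proportional to OutBag accuracy.

## Fusion and threshold fitting

The power mean f_α is evaluated in log space
(`exp(logsumexp(α·log k)/α)`), with |α| < 1e-6 routed to the geometric
limit `exp(mean(log k))`, so exponents up to the ±20 default bounds neither
overflow nor lose the min/max asymptotics.

All OutBag replicas are aggregated **without deduplication** (a sample in
several OutBags appears once per occurrence) and scored by all N learners,
giving an occurrence × N score matrix. The threshold error of the rule
"predict the high-score class iff fused score ≥ μ" is

    P_e(α, μ) = P(w_hi)·F_hi(μ) + P(w_lo)·(1 − F_lo(μ)),

with the orientation (which class is high-score) chosen per α by comparing
class mean fused scores, priors the empirical OutBag frequencies, and ties
at μ assigned to the high-score class. `estimate_pe` evaluates the F_j as
**exact empirical step CDFs**, making P_e identically the per-sample
misclassification count — a property the test suite checks against a
brute-force loop. The Freedman–Diaconis histogram CDFs (floor of 10 bins,
linearly interpolated) are retained on the fitted model as the reported
per-class score distributions but are not the optimization objective:
optimizing the smoothed CDF and then asserting equality with counting
error would be self-contradictory.

The joint search over (α, μ) ∈ alpha_bounds × (0, 1) uses seeded
differential evolution (Sobol initialization, no polish) within
`optimizer_budget` objective evaluations (default 200, minimum 10), then
refines μ exactly — a vectorized scan over all candidate cuts — at the DE
exponent and at α = 1. The better of the two becomes (α_opt, μ_opt). Since
the α = 1 candidate is always evaluated, the fitted combiner's OutBag
error never exceeds the arithmetic mean's best-threshold error: the
dominance contract is structural, not an optimizer promise. Fit and
predict are fully deterministic given the config seed.

## Evaluation harness

Accuracy, recall, precision and F1 come from the confusion matrix of an
explicit positive class (for glioma cohorts the majority high-grade class
is the conventional choice). Cross-validation is stratified k-fold with
metrics computed from the **pooled** out-of-fold confusion matrix (micro
pooling); pooling is what makes a table's F1 exactly the harmonic mean of
its printed recall and precision, which the published 22-row reference
table satisfies to two decimals. Undefined metrics (zero denominators)
are NaN, never silently 0.

The 21 baseline configurations are mapped to scikit-learn equivalents
(SVMs with Gaussian kernel scale s → gamma = 1/s², "automatic" scale →
`gamma="scale"`, MATLAB max-splits m → `max_leaf_nodes=m+1`, subspace
dimension clamped to the feature count). Two have no direct equivalent and
are implemented in-package: a kernel-density naive Bayes and a
balanced-undersample AdaBoost standing in for RUSBoost. Exact replication
of another toolbox's internals is out of scope; the registry documents
each mapping.

The across-model summary reports mean, sample SD, and a one-sample KS
test of the standardized metric values against the standard normal.
Because the values are standardized with estimated parameters this is a
Lilliefors-style screen; the p-value is reported, not calibrated against
any external figure. Constant columns are flagged as undefined.

## Synthetic generators

* **Feature tables** are drawn from two 8-variate Gaussians with shared
  diagonal covariance, then mapped onto the feature constraints
  (mean-presence columns clipped at 0, ratio columns renormalized to the
  simplex). The default places the low-grade profile at plausible values
  (e.g. composition 0.26/0.12/0.46/0.16 with edema dominant) and shifts
  the high-grade class along a unit direction spread evenly over all 8
  standardized features — raising enhancement and necrosis, shrinking the
  edema share — scaled so the Mahalanobis distance Δ gives the requested
  closed-form Bayes error Φ(−Δ/2) (default 0.05, Δ = 3.29). The ratio
  shifts sum to zero, so simplex renormalization preserves them; with the
  default standard deviations the clipping is essentially never active,
  and a plain LDA on the constrained data attains the closed-form error
  within ±0.02 (tested). The closed form describes the underlying
  Gaussians; `monte_carlo_bayes_error` verifies it by simulating the
  optimal rule. The default cohort size mimics the study scale: 275
  subjects at 55/220 class imbalance.
* **Volumes** place a fixed number of tumor voxels per slice over
  consecutive central slices, with per-class descriptor compositions
  (low-grade edema-dominant, high-grade enhancement-dominant). Counts are
  multinomial (or exact largest-remainder apportionment in deterministic
  mode); the generator returns the hand-counted truth of the actually
  placed voxels, so extractor tests are exact, not statistical.
* **Fusion testbeds** produce score matrices where the optimal exponent is
  known by construction. In the `outlier-min` regime positive samples
  score in (0.52, 0.60) on every base while negatives score in
  (0.40, 0.48) except one contaminant base per sample in (0.92, 0.98):
  the min rule (and, symmetrically, the max rule with flipped
  orientation) separates perfectly while the arithmetic mean overlaps by
  a margin the generator measures and reports.

What the generators do *not* emulate: real MRI intensity or texture,
spatial correlation of labels, inter-rater segmentation noise, or the
actual BRATS2015 feature distributions. Passing tests therefore certify
the algorithmic contracts — not clinical performance, which requires the
external cohort.

## Problem sizes and numerical choices

The performance checks train N = 100 learners on 400 samples and test on
1000, averaged over 10 seeds — large enough for the Monte-Carlo bands used
(±0.05 around the 0.05 Bayes target) while keeping a full run in minutes
on one core. Optimizer budget 200 evaluations (150 for the 5-base
testbeds); α bounds ±20, beyond which the clipped-score power mean is
numerically min/max. Score clipping ε = 1e-6; geometric-limit switch at
|α| < 1e-6; ratio-sum validation tolerance 1e-6 on read, 1e-9 in the
extractor's own invariant tests.

## Known limitations

Two-class problems only (the threshold rule is inherently binary);
linear-discriminant base learners only; the weighted power mean is
available but off by default since the unweighted combiner is the primary
formulation; model JSON stores full index bookkeeping, so files grow
linearly with N and n; CDF histograms are summaries, not the decision
machinery.
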