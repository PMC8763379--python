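# Methods

This note documents the models, conventions and numerical choices behind
`smglab`, and what the synthetic data can and cannot establish.

## Synthetic image model

The generator is phenomenological, not acoustic. A dataset's resting image
is a fixed "speckle" texture: white Gaussian noise smoothed with a Gaussian
kernel (`speckle_smoothness`, default 3 px correlation length) and mapped
into [0, 1]. Each motion class is a deformation template — two smooth random
displacement fields (row/column, `warp_smoothness` = 12 px) normalized to
unit RMS and scaled by `class_separation` (RMS displacement in pixels), plus
a local intensity modulation scaled by `intensity_gain · class_separation`.
Frames are produced by bilinear warping of the base texture by a fraction
*s* of the field (*s* ramps 0→1 over the 1-s move segment, holds at 1, ramps
back, rests at 0), then adding i.i.d. Gaussian frame noise (`frame_noise`)
and clipping to [0, 1].

Repetition-level variability multiplies the template amplitude by
`1 + N(0, rep_jitter)` and shifts its spatial center by
`N(0, rep_jitter · rep_shift_scale)` pixels, so each repetition forms its
own sub-cluster around the class cluster — the structure the within-class
distance metric assumes.

Every randomness source (base texture, per-class template, per-repetition
perturbation, per-frame noise) draws from its own named substream of the
config seed, so outputs are bit-reproducible and a class's template does not
depend on how many classes or repetitions are generated, and the emitted
frames do not depend on which cue-cycle segments are materialized.

Default conditions: 5 motion classes × 5 repetitions, 100×140-pixel frames,
10 frames/s (so 10 hold and 10 rest frames per repetition — the protocol
does not pin down how many frames per hold enter a dataset, so the count is
exposed through `frame_rate` and the 1-s cycle segments), `class_separation`
= 0.8 px, `rep_jitter` = 0.45, `frame_noise` = 0.10. The three dials were
chosen once so that default datasets are realistically hard: leave-one-out
accuracy lands in the low-to-mid 90s with several points of seed-to-seed
spread, comparable to what trained users of such systems achieve, rather
than saturating at 100%.

What the generator does *not* emulate: acoustic point-spread functions,
attenuation, shadowing, transducer motion or physiological drift. Passing
tests on this data therefore establishes the correctness and calibration of
the *analysis* (classifier, metrics, statistics), not the field performance
of sonomyography on clinical images.

## Classifier

Frames are flattened to pixel vectors and compared by sample Pearson
correlation; correlations are averaged within each training class and the
class with the highest mean wins (nearest *class*, not nearest image). Ties
break deterministically toward the earliest class in sorted label order.
Zero-variance frames get correlation 0 with a warning rather than an
exception, so degenerate synthetic edge cases cannot abort a whole
cross-validation run.

Leave-one-out cross-validation holds out one *frame* at a time (the
cross-validation unit is a data point); a stricter repetition-level holdout
is available for data whose frames are strongly dependent within a
repetition. Rest frames are excluded from classification by default — the
motions are the classes — but can be included as an extra class. The
implementation is a single correlation-matrix computation with class-sum
corrections; tests verify exact agreement with a brute-force double loop.

## Feature space and cluster metrics

PCA is fitted on all selected frames of one dataset (mean-centered, full SVD
solver, deterministic) and the top five scores are kept. Cluster statistics
use the sample covariance (ddof = 1). Conventions that the source equations
leave open or garble, resolved here by symmetry:

- the two directed half-Mahalanobis distances of a pair use each cluster's
  *own* covariance; the second direction uses the mean difference
  (μ_j − μ_i), mirroring the first;
- the IDAN across-class mean is reported as `IDAN_total` (its defining sum
  runs over IDAN values);
- nearest-neighbor minima run over all classes i ≠ j;
- the 0/0 combined distance of coincident clusters (including the r = k
  self-pairs of WD's ordered-pair sum) is 0.

WD sums combined distances over *ordered* repetition pairs, so each
unordered pair contributes twice. MSD evaluates the combined distance per
single feature axis, using each class's own variance along that axis, takes
the best axis per class pair and then the nearest neighbor. MSA uses 1-σ
semi-axes — square roots of covariance eigenvalues — combined by geometric
mean; the semi-axis scale factor is configurable (`axis_scale`) since
confidence-ellipsoid conventions vary.

Covariances are regularized as `S + λ·tr(S)/d·I` with λ = 1e-6 by default;
per-repetition clouds (10 points in 5-D at default settings) can be nearly
singular, and study-scale runs should never abort on a degenerate cluster.
λ = 0 disables the ridge, and all oracle-equivalence and affine-invariance
tests run unregularized: WD, IDNN and IDAN are invariant under any
invertible affine map of the feature points, MSD under axis permutations,
and MSA is homogeneous of degree 1 under scaling.

## Mixed models and permutation inference

Outcomes over a study (CA and the five metric totals, one row per dataset)
are modeled as `Y_ij = β₀ + b_i + β'X_ij + ε_ij` with a subject random
intercept. Fitting is maximum likelihood, *not* REML, so refits under
permuted fixed effects are on a comparable likelihood scale. The built-in
fitter profiles the variance ratio ρ = σ_b²/σ_ε²: for each ρ the GLS
estimates and residual variance come in closed form via the Sherman–Morrison
identity per subject block, leaving a bounded 1-D minimization over log ρ
(with the ρ = 0 boundary checked explicitly). A fit costs well under a
millisecond at study sizes, which is what makes large permutation ensembles
affordable; `fit_lmm(..., method="statsmodels")` fits the identical model
through `MixedLM`, and the test suite asserts agreement of coefficients,
variance components and log-likelihood.

The permutation test shuffles the tested covariate's values *within each
subject* (preserving the grouping structure and all other columns), refits,
and ranks the observed coefficient t-ratio (estimate/SE — approximately
pivotal) among the permuted ones with the add-one rule
`p = (1 + b)/(1 + m)`, so p ∈ [1/(m+1), 1]. One-sided tests rank signed
statistics, two-sided absolute values. A covariate that is constant within
every subject cannot be tested this way and is rejected with an error. A
constant outcome yields tied statistics and p = 1 by construction.
Normalized time is computed per subject as (t − t_first)/(t_last − t_first);
with the default measurement schedule — three baseline datasets 20 min
apart, a 30-min instruction break, three feedback datasets — phase and
normalized time correlate at ≈ 0.94, which is why the two never enter one
model together.

## Biofeedback trace

The display value is v_t = 1 − r(frame_t, frame_0), so the initial rest
frame maps to exactly 0, uncorrelated frames to ≈ 1 and anticorrelated
frames to 2; the alternative −r mapping is available since the original
display's axis scaling is a presentation choice. The plateau score is the
population standard deviation of v over a hold window (lower = steadier).

## Pipeline and problem sizes

`run_experiment` simulates a two-phase study (default 5 subjects × 3
baseline + 3 feedback datasets); the feedback phase multiplies
`class_separation` by 1.3 and `rep_jitter` by 0.7, emulating a user who
improves with coaching. One top-level seed fans out into named substreams
per subject/dataset/stage. The acceptance script runs the study at
50×70-pixel frames (full 100×140 for the single-dataset analysis) — frame
size mostly rescales compute, not the cluster geometry, since the warp
statistics are resolution-independent at these scales. Test-suite
simulations use 32×44 to 50×70 frames and seed counts (20–1000 depending on
the property) chosen to make Monte-Carlo noise small relative to the
asserted tolerances.

## Known limitations

- The image model has no acoustic physics; absolute metric magnitudes are
  not comparable to clinical ultrasound, only their orderings and responses
  to the generator dials are meaningful.
- The profiled fitter covers exactly one random effect (the subject
  intercept); random slopes or crossed effects are out of scope.
- Permutation inference assumes within-subject exchangeability of the tested
  covariate under the null; strong serial correlation within subjects would
  violate it.
- MSA depends on the semi-axis convention; only ratios across phases or
  sessions are interpretable, not absolute values.
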