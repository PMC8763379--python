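# smglab

Sonomyography (SMG) senses muscle deformation with B-mode ultrasound and uses
it as a control source for upper-limb prostheses: a transducer on the residual
limb images the forearm muscles while the user attempts hand gestures, and a
classifier maps each frame to the intended motion. `smglab` is a tested,
reusable implementation of the analysis pipeline behind this kind of study,
aimed at researchers in prosthetics, rehabilitation engineering and
biosignal pattern recognition. It provides:

- **Synthetic data generation** — speckle-textured ultrasound-like frame
  sequences following the cued protocol (1 s move, 1 s hold, 1 s return, 1 s
  rest; five repetitions of each of five motions per dataset), with dials for
  class separability, repetition consistency and frame noise; plus
  longitudinal outcome tables drawn from a random-intercept model.
- **Classification** — a modified 1-nearest-neighbor rule: the Pearson
  correlation between the query frame's pixel vector and each training frame
  is averaged *by class*, and the most similar class wins. Leave-one-out
  cross-validation yields the cross-validation accuracy
  `CA = 100 · P_correct / P_total` and a confusion matrix.
- **Feature-space metrics** — each 100×140 frame is a point in 14,000-D
  pixel space, reduced to 5-D by PCA. Motion clusters are summarized by
  within-class distance (WD), inter-class distance to the nearest / all
  neighbors (IDNN / IDAN), most separable dimension (MSD) and mean
  semi-principal axis (MSA), all built from half Mahalanobis distances
  `d(a→b) = ½√((μ_a−μ_b)ᵀ S_a⁻¹ (μ_a−μ_b))` pooled symmetrically as
  `d_ab·d_ba/(d_ab+d_ba)`.
- **Statistics** — random-intercept linear mixed models
  `Y_ij = β₀ + b_i + β₁X_ij + ε_ij` relating outcomes to experimental phase,
  session or elapsed time, with significance from within-subject permutation
  tests (default 1000 permutations, add-one p-values).
- **Biofeedback trace** — the real-time consistency display: inverted Pearson
  correlation of each incoming frame against the sequence's initial rest
  frame, plus a plateau-consistency score for hold periods.

## Worked example

```python
from smglab import (ImageGenConfig, generate_dataset, loo_cross_validate,
                    fit_project_pca, compute_metrics)

cfg = ImageGenConfig(seed=7)           # 5 motions x 5 reps, 100x140 px, 10 fps
ds = generate_dataset(cfg, roles=("hold", "rest"))
cv = loo_cross_validate(ds)            # leave-one-frame-out, rest excluded
print(f"CA = {cv.accuracy:.1f}%  ({cv.p_correct}/{cv.p_total})")

cloud = fit_project_pca(ds)            # 14,000-D pixel vectors -> 5-D PCA
ms = compute_metrics(cloud)
print({k: round(v, 3) for k, v in ms.totals.items()})
```

prints

```
CA = 96.0%  (240/250)
{'WD_total': 308.446, 'IDNN_total': 12.973, 'IDAN_total': 60.092,
 'MSD_total': 0.878, 'MSA_total': 0.225}
```

Of the 250 held-out end-state frames, 240 were assigned to the correct
motion (the confusion matrix shows the ten errors are index-point frames
mistaken for key grasp). The metric totals say the five motion clusters sit
well apart relative to their spread (IDNN ≈ 13) while repetitions of the
same motion still scatter (WD ≈ 308, driven by the default repetition
jitter); MSA ≈ 0.23 is the geometric-mean 1-σ radius of a motion cluster in
PCA score units.

A full simulated training study — several subjects, three baseline datasets,
then three feedback datasets with better separability/consistency, ending in
permutation-tested mixed models per outcome — runs via

```python
from smglab import RunConfig, run_experiment
report = run_experiment(RunConfig(seed=1))
```

or from the shell with `smg run`. The `smg` CLI also exposes the individual
stages (`simulate`, `classify`, `features`, `stats`, `feedback`, `convert`,
`validate`); see `smg --help`.

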