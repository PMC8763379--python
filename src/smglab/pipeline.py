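"""End-to-end experiment orchestration: simulate -> classify -> features -> stats.

``run_experiment`` reproduces the shape of a biofeedback training study: each
subject records ``datasets_per_phase`` datasets during a *baseline* phase and
again during a *feedback* phase later the same day.  Each dataset is
generated, classified with leave-one-out cross-validation, and summarized by
the five feature-space metrics; the resulting longitudinal table of outcomes
is then fed to the random-intercept mixed model with a permutation test on
the phase effect.  The feedback phase can be made genuinely "better"
(larger class separation, less repetition jitter) to emulate a user learning
from the display.

A single top-level seed fans out into named substreams per subject, dataset
and stage, so any stage can be rerun in isolation and reproduce its part of
the experiment.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import loo_cross_validate
from .features import compute_metrics, fit_project_pca, METRIC_NAMES
from .lmm import LMMSpec, fit_lmm, normalized_time, permutation_pvalue
from .synthetic import ImageGenConfig, measurement_times

log = logging.getLogger("smglab")

OUTCOME_COLUMNS = ("CA", "WD", "IDNN", "IDAN", "MSD", "MSA")


@dataclass
class RunConfig:
    """Configuration of a full simulated training experiment."""

    n_subjects: int = 5
    datasets_per_phase: int = 3
    image: ImageGenConfig = field(default_factory=ImageGenConfig)
    # multiplicative changes applied to the generator during the feedback
    # phase, emulating improved separability / consistency after coaching
    feedback_separation_gain: float = 1.3
    feedback_jitter_factor: float = 0.7
    dataset_spacing_min: float = 20.0
    phase_break_min: float = 30.0
    include_rest: bool = False
    holdout: str = "frame"
    n_components: int = 5
    covariance_reg: float = 1e-6
    n_permutations: int = 1000
    sidedness: str = "greater"   # one-sided: did the outcome increase with feedback?
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        img = ImageGenConfig(**raw.pop("image", {}))
        return cls(image=img, **raw)


def _stage_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def analyze_dataset(dataset, include_rest=False, holdout="frame",
                    n_components=5, reg=1e-6) -> dict:
    """CA plus feature-space metric totals for one motion dataset."""
    cv = loo_cross_validate(dataset, include_rest=include_rest, holdout=holdout)
    cloud = fit_project_pca(dataset, n_components=n_components,
                            include_rest=include_rest)
    metrics = compute_metrics(cloud, reg=reg)
    out = {"CA": cv.accuracy}
    out.update({k: metrics.totals[f"{k}_total"] for k in METRIC_NAMES})
    out["confusion"] = cv.confusion.values.tolist()
    out["class_order"] = cv.class_order
    return out


def run_experiment(config: RunConfig, outdir=None) -> dict:
    """Execute the full simulated study and return (optionally write) a report."""
    t0 = time.perf_counter()
    m = 2 * config.datasets_per_phase
    times = measurement_times(m, config.dataset_spacing_min, config.phase_break_min)
    rows = []
    for si in range(config.n_subjects):
        subject = f"s{si + 1}"
        for di in range(m):
            phase = "baseline" if di < config.datasets_per_phase else "feedback"
            img = config.image
            if phase == "feedback":
                img = img.with_(
                    class_separation=img.class_separation * config.feedback_separation_gain,
                    rep_jitter=img.rep_jitter * config.feedback_jitter_factor,
                )
            img = img.with_(seed=_stage_seed(config.seed, si, di))
            t_gen = time.perf_counter()
            from .synthetic import generate_dataset

            ds = generate_dataset(img, subject=subject, phase=phase,
                                  roles=("hold", "rest"))
            try:
                res = analyze_dataset(ds, config.include_rest, config.holdout,
                                      config.n_components, config.covariance_reg)
            except Exception as exc:
                raise RuntimeError(
                    f"classifier/feature stage failed for subject {subject} "
                    f"dataset {di + 1}: {exc}"
                ) from exc
            log.info("subject %s dataset %d (%s): CA=%.1f%% [%.2fs]",
                     subject, di + 1, phase, res["CA"],
                     time.perf_counter() - t_gen)
            rows.append(dict(subject=subject, dataset=di + 1, phase=phase,
                             phase01=float(phase == "feedback"),
                             time_min=times[di],
                             **{k: res[k] for k in OUTCOME_COLUMNS}))
    table = pd.DataFrame(rows)
    table["time_norm"] = normalized_time(table, "time_min", "subject")

    lmm_results = {}
    rng = np.random.default_rng(_stage_seed(config.seed, 999))
    for outcome in OUTCOME_COLUMNS:
        spec = LMMSpec(outcome=outcome, covariates=("phase01",),
                       group="subject", test_covariate="phase01",
                       sidedness=config.sidedness,
                       n_permutations=config.n_permutations,
                       seed=config.seed)
        fit = fit_lmm(table, spec)
        p, t_obs = permutation_pvalue(table, spec, rng=rng)
        lmm_results[outcome] = dict(
            beta0=float(fit.params["const"]),
            beta_phase=float(fit.params["phase01"]),
            sigma_b=fit.sigma_b, sigma_eps=fit.sigma_eps,
            t_observed=t_obs, p_permutation=p,
        )
        log.info("LMM %s: phase effect %+.3f (perm p=%.4f)",
                 outcome, fit.params["phase01"], p)

    phase_time_corr = float(np.corrcoef(table["phase01"], table["time_norm"])[0, 1])
    report = dict(
        config=_config_dict(config),
        outcomes=table.to_dict(orient="records"),
        lmm=lmm_results,
        phase_time_correlation=phase_time_corr,
        elapsed_s=time.perf_counter() - t0,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "outcomes.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        log.info("report written to %s", outdir)
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["image"] = asdict(config.image)
    return d
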