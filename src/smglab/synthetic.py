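"""Synthetic sonomyography frame sequences and longitudinal outcome series.

No public ultrasound dataset accompanies this pipeline, so every downstream
stage is exercised on generated data.  The image model is deliberately
phenomenological rather than acoustic: a fixed speckle-like base texture
(spatially smoothed white noise) stands in for the resting B-mode image, and
each motion class is a smooth random warp field plus a local intensity
modulation applied to that texture, standing in for the muscle deformation at
the motion's end state.  Repetitions of a motion perturb the class field
(amplitude jitter and a small spatial offset of the deformation center) and
every frame receives independent additive noise.  The cue cycle mirrors the
acquisition protocol: 1 s move, 1 s hold at the end state, 1 s return, 1 s
rest, repeated five times per motion.

Three dials map onto the quantities the analysis measures:

* ``class_separation`` (RMS warp displacement, pixels) controls how far apart
  motion clusters land in feature space (separability, IDNN/IDAN/MSD);
* ``rep_jitter`` controls repetition-to-repetition variability of one motion
  (consistency, WD);
* ``frame_noise`` controls per-frame noise, i.e. the within-repetition spread.

The outcome generator draws longitudinal study tables from a random-intercept
model Y_ij = beta0 + b_i + beta1 * X_ij + eps_ij for testing the mixed-model
stage under known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates, shift as nd_shift

from .dataset import DEFAULT_CYCLE, REST_LABEL, FrameRecord, MotionDataset, cycle_frame_counts

#: ``class_id`` value that denotes the rest state (zero deformation field).
REST_INDEX = -1

#: Default motion names for the standard five-gesture set.
DEFAULT_MOTIONS = ("power_grasp", "wrist_pronation", "key_grasp", "tripod", "index_point")

# substream tags so each randomness source has its own deterministic stream
_BASE, _TEMPLATE, _REP, _NOISE, _OUTCOME = 11, 22, 33, 44, 55


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


@dataclass(frozen=True)
class ImageGenConfig:
    """Parameters of the synthetic frame generator.

    ``class_separation`` is the RMS displacement (in pixels) of a class's warp
    field; 0 makes every class identical to rest.  ``rep_jitter`` is the
    standard deviation of the repetition-level amplitude perturbation (also
    scaled into a center offset); ``frame_noise`` the std of per-frame
    additive Gaussian noise; ``speckle_smoothness`` the correlation length of
    the base texture in pixels.  A given (config, seed) pair reproduces the
    same dataset bit for bit.
    """

    n_classes: int = 5
    n_repetitions: int = 5
    frame_height: int = 100
    frame_width: int = 140
    frame_rate: float = 10.0
    class_separation: float = 0.8
    rep_jitter: float = 0.45
    frame_noise: float = 0.10
    speckle_smoothness: float = 3.0
    warp_smoothness: float = 12.0
    intensity_gain: float = 0.05
    rep_shift_scale: float = 2.0
    cycle: tuple[float, float, float, float] = DEFAULT_CYCLE
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_repetitions) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.frame_height, self.frame_width) < 1:
            raise ValueError("frame dimensions must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for name in ("class_separation", "rep_jitter", "frame_noise",
                     "speckle_smoothness", "intensity_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kw) -> "ImageGenConfig":
        return replace(self, **kw)


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    """Unit-RMS spatially correlated Gaussian field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=smoothness, mode="reflect")
    rms = np.sqrt(np.mean(f * f))
    return f / rms if rms > 0 else f


def base_speckle(cfg: ImageGenConfig) -> np.ndarray:
    """Resting-state texture: smoothed white noise mapped into [0, 1]."""
    rng = _rng(cfg.seed, _BASE)
    f = _smooth_field(rng, (cfg.frame_height, cfg.frame_width), cfg.speckle_smoothness)
    return np.clip(0.5 + 0.15 * f, 0.0, 1.0)


def make_class_template(cfg: ImageGenConfig, class_id: int) -> np.ndarray:
    """Deformation field of one motion class.

    Returns a ``(3, H, W)`` stack: row displacement, column displacement (both
    RMS-normalized then scaled by ``class_separation``) and an intensity
    modulation (scaled by ``intensity_gain * class_separation``).  The
    reserved :data:`REST_INDEX` yields the all-zero field.  Fields are drawn
    from a per-class substream, so each class's template is independent of
    how many other classes exist.
    """
    shape = (cfg.frame_height, cfg.frame_width)
    if class_id == REST_INDEX:
        return np.zeros((3,) + shape)
    if not 0 <= class_id < cfg.n_classes:
        raise IndexError(f"class_id {class_id} outside [0, {cfg.n_classes})")
    if cfg.class_separation == 0:
        return np.zeros((3,) + shape)
    rng = _rng(cfg.seed, _TEMPLATE, class_id)
    dy = cfg.class_separation * _smooth_field(rng, shape, cfg.warp_smoothness)
    dx = cfg.class_separation * _smooth_field(rng, shape, cfg.warp_smoothness)
    di = cfg.intensity_gain * cfg.class_separation * _smooth_field(rng, shape, cfg.warp_smoothness)
    return np.stack([dy, dx, di])


def _repetition_field(cfg: ImageGenConfig, template: np.ndarray,
                      class_id: int, rep: int) -> np.ndarray:
    """Perturb a class template for one repetition.

    The amplitude is scaled by ``1 + N(0, rep_jitter)`` and the field's
    spatial center shifts by ``N(0, rep_jitter * rep_shift_scale)`` pixels,
    yielding distinct but clustered repetition sub-clouds.
    """
    if cfg.rep_jitter == 0:
        return template
    rng = _rng(cfg.seed, _REP, class_id, rep)
    amp = 1.0 + cfg.rep_jitter * rng.standard_normal()
    offset = cfg.rep_jitter * cfg.rep_shift_scale * rng.standard_normal(2)
    if not np.any(template):
        return template
    shifted = np.stack([
        nd_shift(template[k], offset, order=1, mode="nearest") for k in range(3)
    ])
    return amp * shifted


def _warp(base: np.ndarray, fld: np.ndarray, s: float, grid) -> np.ndarray:
    """Apply fraction ``s`` of a deformation field to the base texture."""
    if s == 0.0 or not np.any(fld):
        return base + s * fld[2]
    Y, X = grid
    warped = map_coordinates(base, [Y - s * fld[0], X - s * fld[1]],
                             order=1, mode="reflect")
    return warped + s * fld[2]


def _segment_progress(counts: Sequence[int]):
    """Per-frame (role, deformation fraction) across one cue cycle."""
    n_move, n_hold, n_ret, n_rest = counts
    out = []
    out += [("move", (t + 1) / n_move) for t in range(n_move)]
    out += [("hold", 1.0)] * n_hold
    out += [("return", 1.0 - (t + 1) / n_ret) for t in range(n_ret)]
    out += [("rest", 0.0)] * n_rest
    return out


def generate_dataset(
    cfg: ImageGenConfig,
    subject: str = "s1",
    session: int = 1,
    phase: str = "none",
    class_names: Sequence[str] | None = None,
    roles: tuple[str, ...] = ("move", "hold", "return", "rest"),
) -> MotionDataset:
    """Generate one complete motion dataset under the cue-cycle protocol.

    For every (class, repetition) pair a full move/hold/return/rest sequence
    is synthesized at ``cfg.frame_rate``; ``roles`` restricts which segments
    are materialized (sweeps that only need hold and rest frames can skip the
    transitions).  Hold frames are the base texture warped by the
    repetition's deformation field plus frame noise; rest frames are texture
    plus noise.  Intensities are clipped to [0, 1].
    """
    if class_names is None:
        class_names = (DEFAULT_MOTIONS if cfg.n_classes == len(DEFAULT_MOTIONS)
                       else tuple(f"motion{c + 1}" for c in range(cfg.n_classes)))
    if len(class_names) != cfg.n_classes:
        raise ValueError("class_names length must equal n_classes")
    base = base_speckle(cfg)
    grid = np.mgrid[0:cfg.frame_height, 0:cfg.frame_width].astype(np.float64)
    counts = cycle_frame_counts(cfg.frame_rate, cfg.cycle)
    plan = _segment_progress(counts)
    frames: list[FrameRecord] = []
    for c in range(cfg.n_classes):
        template = make_class_template(cfg, c)
        for r in range(cfg.n_repetitions):
            fld = _repetition_field(cfg, template, c, r)
            noise_rng = _rng(cfg.seed, _NOISE, c, r)
            cache: dict[float, np.ndarray] = {}
            for t, (role, s) in enumerate(plan):
                # noise stream advances for every planned frame so the
                # emitted pixels do not depend on the `roles` selection
                noise = (cfg.frame_noise * noise_rng.standard_normal(base.shape)
                         if cfg.frame_noise > 0 else 0.0)
                if role not in roles:
                    continue
                if s not in cache:
                    cache[s] = _warp(base, fld, s, grid)
                img = np.clip(cache[s] + noise, 0.0, 1.0)
                frames.append(FrameRecord(
                    pixels=img, subject=subject, session=session, phase=phase,
                    motion=REST_LABEL if role == "rest" else class_names[c],
                    repetition=r + 1, role=role, frame_index=t,
                ))
    return MotionDataset(
        frames, n_motions=cfg.n_classes, n_repetitions=cfg.n_repetitions,
        metadata=dict(subject=subject, session=session, phase=phase,
                      generator="smglab.synthetic", seed=cfg.seed),
    )


# ---------------------------------------------------------------------------
# longitudinal outcome series
# ---------------------------------------------------------------------------

#: Session-clock measurement times (minutes) for the standard 6-measurement
#: day: three baseline datasets, a setup/instruction break, three feedback
#: datasets.  The break is what drives phase and elapsed time to be highly
#: collinear rather than perfectly confounded.
DEFAULT_TIMES_MIN = (0.0, 20.0, 40.0, 90.0, 110.0, 130.0)


@dataclass(frozen=True)
class OutcomeGenConfig:
    """Random-intercept generator for outcome metrics over a study.

    ``covariate_kind`` chooses the fixed effect that carries ``beta1``:
    ``"phase"`` (0 baseline / 1 feedback), ``"time"`` (per-subject normalized
    elapsed time in [0, 1]) or ``"both"`` (beta1 on phase; both columns
    emitted so collinearity between them can be studied).
    """

    n_subjects: int = 8
    n_measurements: int = 6
    beta0: float = 90.0
    beta1: float = 3.0
    sigma_b: float = 2.0
    sigma_eps: float = 1.0
    covariate_kind: str = "phase"
    times_min: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_eps < 0:
            raise ValueError("sigma_b and sigma_eps must be >= 0")
        if self.n_subjects < 1 or self.n_measurements < 2:
            raise ValueError("need >= 1 subject and >= 2 measurements")
        if self.covariate_kind not in ("phase", "time", "both"):
            raise ValueError("covariate_kind must be 'phase', 'time' or 'both'")


def measurement_times(n_measurements: int, spacing_min: float = 20.0,
                      phase_break_min: float = 30.0) -> np.ndarray:
    """Session-clock times with a break between the two phases."""
    n_base = n_measurements // 2
    t = []
    for j in range(n_measurements):
        extra = phase_break_min if j >= n_base else 0.0
        t.append(j * spacing_min + extra)
    return np.asarray(t)


def generate_outcomes(cfg: OutcomeGenConfig) -> pd.DataFrame:
    """Draw one longitudinal study table from the random-intercept model.

    Columns: subject, measurement (0-based), time_min, phase (0/1),
    time_norm (per-subject normalized time), x (the covariate carrying
    ``beta1``) and y.
    """
    rng = _rng(cfg.seed, _OUTCOME)
    m = cfg.n_measurements
    times = (np.asarray(cfg.times_min, dtype=float) if cfg.times_min is not None
             else (np.asarray(DEFAULT_TIMES_MIN) if m == 6 else measurement_times(m)))
    if len(times) != m:
        raise ValueError("times_min length must equal n_measurements")
    n_base = m // 2
    phase = (np.arange(m) >= n_base).astype(float)
    tnorm = (times - times[0]) / (times[-1] - times[0])
    x = phase if cfg.covariate_kind in ("phase", "both") else tnorm
    rows = []
    for i in range(cfg.n_subjects):
        b_i = cfg.sigma_b * rng.standard_normal()
        eps = cfg.sigma_eps * rng.standard_normal(m)
        y = cfg.beta0 + b_i + cfg.beta1 * x + eps
        for j in range(m):
            rows.append(dict(subject=f"s{i + 1}", measurement=j,
                             time_min=times[j], phase=phase[j],
                             time_norm=tnorm[j], x=x[j], y=y[j]))
    return pd.DataFrame(rows)
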