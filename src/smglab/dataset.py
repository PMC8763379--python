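"""Data model and on-disk formats for labeled sonomyography frame collections.

A sonomyography (SMG) recording is a sequence of grayscale B-mode ultrasound
frames captured while a user performs cued hand motions.  Each cue cycle is
move / hold / return / rest; the frames captured during the 1-s hold (the
"end state") and during rest are the ones the classifier and feature-space
analysis consume.  This module defines the in-memory containers
(:class:`FrameRecord`, :class:`MotionDataset`), area-averaged downscaling,
cue-aligned role extraction, and two interchangeable on-disk dialects:
a directory of 8-bit PNG frames with a CSV manifest, and a single HDF5
container with float frames.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

ROLES = ("move", "hold", "return", "rest")
PHASES = ("baseline", "feedback", "none")

#: Motion label carried by rest-role frames so that "rest" can optionally be
#: treated as its own class downstream.
REST_LABEL = "rest"

#: Manifest columns required by the PNG+CSV dialect, in canonical order.
MANIFEST_COLUMNS = (
    "subject", "session", "phase", "motion", "repetition", "role",
    "frame_index", "path",
)

#: Default cue cycle: 1 s move, 1 s hold, 1 s return, 1 s rest.
DEFAULT_CYCLE = (1.0, 1.0, 1.0, 1.0)


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the expected layout."""


@dataclass
class FrameRecord:
    """One grayscale frame plus its experimental labels.

    ``pixels`` holds floating intensities; files written as 8-bit PNG are
    scaled to [0, 1] on read.  ``role`` says where in the cue cycle the frame
    was captured; ``repetition`` is 1-based.
    """

    pixels: np.ndarray
    subject: str = "s1"
    session: int = 1
    phase: str = "none"
    motion: str = ""
    repetition: int = 1
    role: str = "hold"
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2-D grayscale matrix")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.role not in ROLES:
            raise ValueError(f"role {self.role!r} not in {ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class MotionDataset:
    """All frames of one data-collection dataset (n motions x n repetitions)."""

    frames: list[FrameRecord]
    n_motions: int
    n_repetitions: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("dataset contains no frames")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError(f"frames have inconsistent dimensions: {sorted(shapes)}")
        motions = self.motion_labels
        if len(motions) != self.n_motions:
            raise ValueError(
                f"expected {self.n_motions} motion classes, found {len(motions)}: {motions}"
            )
        present = {(f.motion, f.repetition) for f in self.frames}
        for m in motions:
            for r in range(1, self.n_repetitions + 1):
                if (m, r) not in present:
                    raise ValueError(f"missing frames for motion {m!r} repetition {r}")

    @property
    def motion_labels(self) -> list[str]:
        """Ordered non-rest motion labels (first-appearance order)."""
        seen: dict[str, None] = {}
        for f in self.frames:
            if f.motion != REST_LABEL:
                seen.setdefault(f.motion, None)
        return list(seen)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def select(self, roles: tuple[str, ...] = ("hold",), include_rest: bool = False):
        """Return (pixel matrix, motion labels, repetition labels) for a role subset.

        Frames are flattened to pixel vectors, one row per frame.  Rest-role
        frames are excluded unless ``include_rest`` is set, in which case they
        join under the :data:`REST_LABEL` class.
        """
        picked = [
            f for f in self.frames
            if (f.role in roles and f.motion != REST_LABEL)
            or (include_rest and f.role == "rest")
        ]
        if not picked:
            raise ValueError(f"no frames with roles {roles}")
        X = np.stack([f.pixels.ravel() for f in picked])
        labels = np.array([f.motion for f in picked])
        reps = np.array([f.repetition for f in picked])
        return X, labels, reps


def _overlap_weights(n_src: int, n_dst: int) -> np.ndarray:
    """Row-stochastic matrix averaging ``n_src`` cells into ``n_dst`` intervals.

    Entry (i, j) is the fraction of destination interval i covered by source
    cell j, so a matrix product implements exact area-averaged resampling for
    arbitrary (not just integer) downscale factors.
    """
    edges = np.linspace(0.0, n_src, n_dst + 1)
    W = np.zeros((n_dst, n_src))
    for i in range(n_dst):
        a, b = edges[i], edges[i + 1]
        j0, j1 = int(np.floor(a)), min(int(np.ceil(b)), n_src)
        for j in range(j0, j1):
            W[i, j] = min(b, j + 1.0) - max(a, float(j))
    return W * (n_dst / n_src)


def downscale_frame(pixels: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Area-averaged downscaling of a grayscale frame to ``target_h x target_w``.

    Deterministic, preserves constants, and reduces to exact block means when
    the source dimensions are integer multiples of the target.  Upscaling is
    refused: the operation models cropping a captured screen down to the
    relevant ultrasound region.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    h, w = pixels.shape
    if target_h > h or target_w > w:
        raise ValueError(
            f"cannot upscale: target ({target_h}x{target_w}) exceeds source ({h}x{w})"
        )
    if (target_h, target_w) == (h, w):
        return pixels.copy()
    Wh = _overlap_weights(h, target_h)
    Ww = _overlap_weights(w, target_w)
    return Wh @ pixels @ Ww.T


def cycle_frame_counts(frame_rate: float, cycle=DEFAULT_CYCLE) -> list[int]:
    """Frames per move/hold/return/rest segment at the given frame rate."""
    counts = [int(round(d * frame_rate)) for d in cycle]
    if any(c < 1 for c in counts):
        raise ValueError(f"frame rate {frame_rate} too low for cycle {cycle}")
    return counts


def extract_task_frames(
    sequence,
    frame_rate: float,
    cycle=DEFAULT_CYCLE,
    keep: tuple[str, ...] = ("hold", "rest"),
    subject: str = "s1",
    session: int = 1,
    phase: str = "none",
    motion: str = "",
    start_repetition: int = 1,
) -> list[FrameRecord]:
    """Assign cue-cycle roles to an ordered frame sequence and keep a subset.

    Role windows are half-open [start, end) in frame indices so each frame
    gets exactly one role.  Each full cycle increments the repetition index.
    A truncated final cycle is labeled as far as its windows reach and a
    warning is emitted.  Rest frames carry motion label :data:`REST_LABEL`.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in sequence]
    counts = cycle_frame_counts(frame_rate, cycle)
    cycle_len = sum(counts)
    starts = np.concatenate([[0], np.cumsum(counts)])
    n = len(frames)
    if n % cycle_len:
        warnings.warn(
            f"sequence length {n} is not a whole number of {cycle_len}-frame "
            "cycles; final cycle labeled partially",
            stacklevel=2,
        )
    out: list[FrameRecord] = []
    for t in range(n):
        rep = t // cycle_len
        offset = t % cycle_len
        role = ROLES[int(np.searchsorted(starts, offset, side="right")) - 1]
        if role not in keep:
            continue
        out.append(
            FrameRecord(
                pixels=frames[t],
                subject=subject,
                session=session,
                phase=phase,
                motion=REST_LABEL if role == "rest" else motion,
                repetition=start_repetition + rep,
                role=role,
                frame_index=t,
            )
        )
    return out


# ---------------------------------------------------------------------------
# on-disk dialects
# ---------------------------------------------------------------------------

def save_dataset(dataset: MotionDataset, path) -> None:
    """Write a dataset as PNG+CSV (directory path) or HDF5 (.h5/.hdf5 path)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _save_hdf5(dataset, path)
    else:
        _save_png_dir(dataset, path)


def load_dataset(path) -> MotionDataset:
    """Read a dataset from either on-disk dialect, validating its invariants."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_hdf5(path)
    return _load_png_dir(path)


def _save_png_dir(dataset: MotionDataset, root: Path) -> None:
    import imageio.v3 as iio

    frames_dir = root / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, f in enumerate(dataset.frames):
        name = f"{i:05d}_{f.motion}_r{f.repetition}_{f.role}.png"
        img8 = np.round(np.clip(f.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
        iio.imwrite(frames_dir / name, img8)
        rows.append(
            dict(
                subject=f.subject, session=f.session, phase=f.phase,
                motion=f.motion, repetition=f.repetition, role=f.role,
                frame_index=f.frame_index, path=f"frames/{name}",
            )
        )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(root / "manifest.csv", index=False)
    meta = dict(
        n_motions=dataset.n_motions,
        n_repetitions=dataset.n_repetitions,
        metadata=dataset.metadata,
    )
    (root / "dataset.json").write_text(json.dumps(meta, indent=1))


def _load_png_dir(root: Path) -> MotionDataset:
    import imageio.v3 as iio

    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise FormatError(f"no manifest.csv under {root}")
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing required column(s): {missing}")
    frames = []
    for row in manifest.itertuples(index=False):
        img = iio.imread(root / str(row.path))
        if img.ndim == 3:  # grayscale stored with redundant channels
            img = img[..., 0]
        frames.append(
            FrameRecord(
                pixels=img.astype(np.float64) / 255.0,
                subject=str(row.subject), session=int(row.session),
                phase=str(row.phase), motion=str(row.motion),
                repetition=int(row.repetition), role=str(row.role),
                frame_index=int(row.frame_index),
            )
        )
    meta_path = root / "dataset.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        n_motions, n_reps = meta["n_motions"], meta["n_repetitions"]
        metadata = meta.get("metadata", {})
    else:
        labels = sorted({f.motion for f in frames if f.motion != REST_LABEL})
        n_motions = len(labels)
        n_reps = max(f.repetition for f in frames)
        metadata = {}
    try:
        return MotionDataset(frames, n_motions, n_reps, metadata)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


_STR = h5py.string_dtype(encoding="utf-8")


def _save_hdf5(dataset: MotionDataset, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=np.stack([f.pixels for f in dataset.frames]))
        h5.create_dataset("subject", data=np.array([f.subject for f in dataset.frames], dtype=_STR))
        h5.create_dataset("session", data=np.array([f.session for f in dataset.frames]))
        h5.create_dataset("phase", data=np.array([f.phase for f in dataset.frames], dtype=_STR))
        h5.create_dataset("motion", data=np.array([f.motion for f in dataset.frames], dtype=_STR))
        h5.create_dataset("repetition", data=np.array([f.repetition for f in dataset.frames]))
        h5.create_dataset("role", data=np.array([f.role for f in dataset.frames], dtype=_STR))
        h5.create_dataset("frame_index", data=np.array([f.frame_index for f in dataset.frames]))
        h5.attrs["n_motions"] = dataset.n_motions
        h5.attrs["n_repetitions"] = dataset.n_repetitions
        h5.attrs["metadata_json"] = json.dumps(dataset.metadata)


def _load_hdf5(path: Path) -> MotionDataset:
    with h5py.File(path, "r") as h5:
        required = ("frames", "subject", "session", "phase", "motion",
                    "repetition", "role", "frame_index")
        missing = [k for k in required if k not in h5]
        if missing:
            raise FormatError(f"HDF5 container missing dataset(s): {missing}")
        pixels = h5["frames"][...]

        def decode(name):
            return [s.decode() if isinstance(s, bytes) else str(s) for s in h5[name][...]]

        subject, phase = decode("subject"), decode("phase")
        motion, role = decode("motion"), decode("role")
        session = h5["session"][...]
        repetition = h5["repetition"][...]
        frame_index = h5["frame_index"][...]
        frames = [
            FrameRecord(
                pixels=pixels[i], subject=subject[i], session=int(session[i]),
                phase=phase[i], motion=motion[i], repetition=int(repetition[i]),
                role=role[i], frame_index=int(frame_index[i]),
            )
            for i in range(pixels.shape[0])
        ]
        try:
            return MotionDataset(
                frames,
                int(h5.attrs["n_motions"]),
                int(h5.attrs["n_repetitions"]),
                json.loads(h5.attrs.get("metadata_json", "{}")),
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
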