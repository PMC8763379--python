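"""Real-time consistency display: inverted correlation against the rest frame.

During feedback-phase data collection the user watches a trace derived from
the Pearson correlation between each incoming ultrasound frame and the first
frame of the sequence (captured at rest).  The correlation is inverted so
that rest maps near 0 and a fully developed end-state deformation maps near
1; earlier values stay on screen, so a steady hold shows up as a flat
"plateau" of high values.  The plateau score — the standard deviation of the
trace inside a hold window — quantifies how consistently the deformation was
maintained (lower is steadier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import pearson_similarity


@dataclass
class FeedbackTrace:
    """Per-frame display values of one movement sequence."""

    values: np.ndarray
    frame_rate: float | None = None

    @property
    def times(self) -> np.ndarray | None:
        if self.frame_rate is None:
            return None
        return np.arange(len(self.values)) / self.frame_rate

    def __len__(self) -> int:
        return len(self.values)


def correlation_trace(sequence, frame_rate: float | None = None,
                      mapping: str = "one-minus") -> FeedbackTrace:
    """Dissimilarity-from-rest trace of an ordered frame sequence.

    ``mapping="one-minus"`` displays v_t = 1 - r(frame_t, frame_0), so the
    first frame sits at exactly 0 and an anticorrelated frame at 2;
    ``mapping="neg"`` displays -r.  Values are emitted in frame order, one
    per frame.
    """
    frames = [np.asarray(f, dtype=np.float64) for f in sequence]
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for a feedback trace")
    if mapping not in ("one-minus", "neg"):
        raise ValueError("mapping must be 'one-minus' or 'neg'")
    rest = frames[0]
    r = np.array([pearson_similarity(f, rest) for f in frames])
    values = 1.0 - r if mapping == "one-minus" else -r
    return FeedbackTrace(values=values, frame_rate=frame_rate)


def plateau_score(trace: FeedbackTrace, hold_window: tuple[int, int]) -> float:
    """Population standard deviation of the trace inside ``[start, stop)``.

    A flat plateau (consistent deformation through the hold) scores 0.
    """
    start, stop = hold_window
    if not (0 <= start < stop <= len(trace)):
        raise ValueError(f"hold window {hold_window} outside trace of length {len(trace)}")
    return float(np.std(trace.values[start:stop]))
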