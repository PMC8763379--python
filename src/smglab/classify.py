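"""Class-averaged correlation nearest-class classifier with LOO validation.

The classifier is a modified 1-nearest-neighbor rule for grayscale frames:
the Pearson correlation between the query's pixel vector and every training
frame is averaged *within each motion class*, and the class with the highest
mean correlation wins.  Averaging by class (rather than taking the single
most similar image) makes the decision depend on how the query relates to a
motion's whole cluster of training examples.  Because Pearson correlation is
invariant to positive affine intensity changes, so is the classifier.

Leave-one-out cross-validation removes each frame from its own class's
training pool, classifies it against the rest, and reports the
cross-validation accuracy CA = 100 * P_correct / P_total together with the
confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MotionDataset


def _as_matrix(frames) -> np.ndarray:
    X = np.asarray(frames, dtype=np.float64)
    if X.ndim == 3:  # stack of 2-D frames
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise ValueError("training frames must be a 2-D matrix or a stack of frames")
    return X


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    """Center and unit-normalize each row; zero-variance rows become zero.

    With this normalization the matrix product Z @ Z.T is exactly the sample
    Pearson correlation between pixel vectors, and a zero-variance frame has
    correlation 0 with everything (by convention, with a warning).
    """
    Z = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Z, axis=1)
    flat = norms == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} zero-variance frame(s): similarity defined as 0",
            stacklevel=3,
        )
    norms[flat] = 1.0
    return Z / norms[:, None]


def pearson_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation between two equal-shaped frames' pixels."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    Z = _zscore_rows(np.stack([a.ravel(), b.ravel()]))
    return float(Z[0] @ Z[1])


def class_order_of(labels) -> list:
    """Deterministic class ordering (sorted unique labels)."""
    return sorted(set(map(str, labels)))


def classify_frame(query, train_frames, train_labels, class_order=None):
    """Classify one frame by highest class-averaged Pearson correlation.

    Returns ``(label, mean_similarities)`` where ``mean_similarities`` maps
    each class to the mean correlation between the query and that class's
    training frames.  Ties break toward the earliest class in
    ``class_order`` (sorted label order by default).
    """
    X = _as_matrix(train_frames)
    labels = np.array([str(l) for l in train_labels])
    if len(labels) != X.shape[0]:
        raise ValueError("one label per training frame required")
    order = [str(c) for c in (class_order or class_order_of(labels))]
    counts = {c: int(np.sum(labels == c)) for c in order}
    empty = [c for c in order if counts[c] == 0]
    if empty:
        raise ValueError(f"class(es) with no training frames: {empty}")
    q = np.asarray(query, dtype=np.float64).ravel()
    if q.size != X.shape[1]:
        raise ValueError("query and training frames have different pixel counts")
    Z = _zscore_rows(np.vstack([q[None, :], X]))
    sims = Z[1:] @ Z[0]
    means = {c: float(sims[labels == c].mean()) for c in order}
    best = order[int(np.argmax([means[c] for c in order]))]
    return best, means


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome for one dataset."""

    predictions: np.ndarray
    truths: np.ndarray
    class_order: list
    confusion: pd.DataFrame  # rows: true class, columns: predicted class
    p_correct: int
    p_total: int

    @property
    def accuracy(self) -> float:
        """Cross-validation accuracy in percent: 100 * P_correct / P_total."""
        return 100.0 * self.p_correct / self.p_total

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.confusion.values), index=self.confusion.index)
        return 100.0 * diag / self.confusion.sum(axis=1)

    def to_dict(self) -> dict:
        return dict(
            CA=self.accuracy,
            p_correct=int(self.p_correct),
            p_total=int(self.p_total),
            class_order=list(self.class_order),
            confusion=self.confusion.values.tolist(),
            per_class_accuracy=self.per_class_accuracy.to_dict(),
        )


def _resolve_input(data, include_rest: bool):
    if isinstance(data, MotionDataset):
        return data.select(roles=("hold",), include_rest=include_rest)
    X, labels = data
    return _as_matrix(X), np.array([str(l) for l in labels]), None


def loo_cross_validate(
    data,
    include_rest: bool = False,
    holdout: str = "frame",
) -> CVResult:
    """Leave-one-out cross-validation of the nearest-class classifier.

    ``data`` is either a :class:`~smglab.dataset.MotionDataset` (hold frames
    are classified; rest frames join as a class only with ``include_rest``)
    or a ``(frames, labels)`` pair.  ``holdout="frame"`` removes just the
    held-out frame from its class's pool; ``holdout="repetition"`` removes
    the frame's whole repetition, a stricter protocol for data where frames
    within a repetition are strongly dependent.
    """
    if holdout not in ("frame", "repetition"):
        raise ValueError("holdout must be 'frame' or 'repetition'")
    X, labels, reps = _resolve_input(data, include_rest)
    order = class_order_of(labels)
    n = X.shape[0]
    if len(order) < 2:
        raise ValueError("need at least two classes for classification")
    y_codes = np.array([order.index(l) for l in labels])
    counts = np.bincount(y_codes, minlength=len(order))
    thin = [order[c] for c in range(len(order)) if counts[c] < 2]
    if thin:
        raise ValueError(f"class(es) with fewer than 2 frames: {thin}")

    Z = _zscore_rows(X)
    R = Z @ Z.T  # pairwise Pearson correlations
    onehot = np.zeros((n, len(order)))
    onehot[np.arange(n), y_codes] = 1.0
    class_sums = R @ onehot  # (n, k): sum of sims to each class incl. self

    if holdout == "frame":
        own = class_sums[np.arange(n), y_codes] - np.diag(R)
        denom = np.repeat(counts[None, :].astype(float), n, axis=0)
        means = class_sums.copy()
        means[np.arange(n), y_codes] = own
        denom[np.arange(n), y_codes] = counts[y_codes] - 1.0
        means = means / denom
    else:
        if reps is None:
            raise ValueError("repetition holdout requires repetition labels")
        rep_key = np.array([f"{labels[i]}::{reps[i]}" for i in range(n)])
        means = class_sums / counts[None, :].astype(float)
        for i in range(n):
            mask = (rep_key == rep_key[i])
            pool = counts[y_codes[i]] - int(mask.sum())
            if pool < 1:
                raise ValueError(
                    f"class {labels[i]!r} has no frames outside repetition {reps[i]}"
                )
            means[i, y_codes[i]] = (class_sums[i, y_codes[i]] - R[i, mask].sum()) / pool

    pred_codes = np.argmax(means, axis=1)  # argmax takes the lowest index on ties
    predictions = np.array([order[c] for c in pred_codes])
    confusion = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for t, p in zip(y_codes, pred_codes):
        confusion.iloc[t, p] += 1
    p_correct = int(np.sum(pred_codes == y_codes))
    return CVResult(
        predictions=predictions,
        truths=np.asarray(labels),
        class_order=order,
        confusion=confusion,
        p_correct=p_correct,
        p_total=n,
    )
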