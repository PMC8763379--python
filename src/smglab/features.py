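"""PCA feature space and cluster consistency/separability metrics.

Each frame's pixel vector (14,000-dimensional at the default 100x140 frame
size) is projected onto the top five principal components fitted on all
frames of a dataset.  In that 5-D space, every motion class forms a point
cloud whose geometry is summarized by five metrics:

* **WD** (within-class distance): summed symmetric combined distances between
  all ordered pairs of a motion's repetition sub-clusters — small when the
  user performs a motion the same way every repetition.
* **IDNN** / **IDAN** (inter-class distance, nearest / all neighbors):
  combined distance from a motion's cluster to its closest other motion, or
  summed over all other motions — large when motions are well separated.
* **MSD** (most separable dimension): nearest-neighbor separability when the
  distance is restricted to the single best of the five feature axes.
* **MSA** (mean semi-principal axis): geometric mean of the cluster
  hyperellipsoid's semi-axes (square roots of covariance eigenvalues) —
  large when a motion's performances are variable.

The building block is the *half Mahalanobis distance* between two cluster
means under the source cluster's covariance,
``d(a->b) = (1/2) * sqrt((mu_a - mu_b)' S_a^{-1} (mu_a - mu_b))``,
and the symmetric pooling ``d_ab * d_ba / (d_ab + d_ba)`` of the two
directions.  Per-class values are averaged into a ``*_total`` across the n
motions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dataset import MotionDataset

#: Default relative ridge added to covariances (lambda in S + lambda*tr(S)/d*I).
DEFAULT_REG = 1e-6

METRIC_NAMES = ("WD", "IDNN", "IDAN", "MSD", "MSA")


@dataclass
class FeatureCloud:
    """PCA-projected frames with class and repetition labels."""

    points: np.ndarray          # (n_frames, n_components) scores
    classes: np.ndarray         # class label per point
    repetitions: np.ndarray     # repetition index per point
    mean_: np.ndarray           # pixel-space mean used for centering
    components_: np.ndarray     # (n_components, n_pixels) PCA basis
    explained_variance_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.points.shape[1]

    @property
    def class_order(self) -> list:
        return sorted(set(map(str, self.classes)))

    def points_of(self, label) -> np.ndarray:
        return self.points[np.asarray(self.classes).astype(str) == str(label)]

    def replace_points(self, points: np.ndarray) -> "FeatureCloud":
        """Same labels, new coordinates (used e.g. for invariance checks)."""
        return FeatureCloud(np.asarray(points, dtype=np.float64),
                            self.classes, self.repetitions,
                            self.mean_, self.components_, self.explained_variance_)


def fit_project_pca(data, n_components: int = 5, include_rest: bool = False) -> FeatureCloud:
    """Fit PCA on all frames of a dataset and project them to ``n_components``.

    ``data`` is a :class:`~smglab.dataset.MotionDataset` (hold frames, rest
    excluded unless requested) or a ``(X, classes, repetitions)`` triple of a
    flattened pixel matrix and labels.  Scores are mean-centered projections
    onto the variance-ordered principal axes.
    """
    if isinstance(data, MotionDataset):
        X, classes, reps = data.select(roles=("hold",), include_rest=include_rest)
    else:
        X, classes, reps = data
        X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < n_components:
        raise ValueError(
            f"{X.shape[0]} frames cannot support {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return FeatureCloud(
        points=scores,
        classes=np.asarray(classes),
        repetitions=np.asarray(reps),
        mean_=pca.mean_,
        components_=pca.components_,
        explained_variance_=pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# cluster statistics and elementary distances
# ---------------------------------------------------------------------------

@dataclass
class ClusterStats:
    """Mean, covariance, and semi-principal axes of one labeled point cloud."""

    mu: np.ndarray
    S: np.ndarray
    axes: np.ndarray   # sqrt of covariance eigenvalues, descending
    n_points: int


def regularize_covariance(S: np.ndarray, reg: float = DEFAULT_REG) -> np.ndarray:
    """Ridge ``S + reg * tr(S)/d * I`` keeping the matrix well conditioned.

    ``reg=0`` disables regularization.  A zero-trace (all points coincident)
    covariance gets an absolute ridge instead so the result is invertible.
    """
    if reg == 0:
        return S
    d = S.shape[0]
    scale = np.trace(S) / d
    if scale <= 0:
        scale = 1.0
    return S + reg * scale * np.eye(d)


def cluster_stats(points: np.ndarray, reg: float = DEFAULT_REG) -> ClusterStats:
    """Sample mean/covariance of a cloud plus hyperellipsoid semi-axes."""
    P = np.asarray(points, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need at least 2 points for a cluster covariance")
    mu = P.mean(axis=0)
    S = np.cov(P, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    if P.shape[0] <= P.shape[1] and reg == 0:
        warnings.warn(
            f"covariance from {P.shape[0]} points in {P.shape[1]}-D is rank "
            "deficient and unregularized", stacklevel=2,
        )
    S = regularize_covariance(S, reg)
    eigvals = np.linalg.eigvalsh(S)
    axes = np.sqrt(np.clip(eigvals, 0.0, None))[::-1]
    return ClusterStats(mu=mu, S=S, axes=axes, n_points=P.shape[0])


def half_mahalanobis(mu_from: np.ndarray, mu_to: np.ndarray, S_from: np.ndarray) -> float:
    """Half the Mahalanobis distance from one cluster mean to another.

    The covariance is the *source* cluster's, so the two directions of a pair
    generally differ; they are pooled by :func:`combined_distance`.
    """
    mu_from = np.asarray(mu_from, dtype=np.float64)
    mu_to = np.asarray(mu_to, dtype=np.float64)
    S_from = np.atleast_2d(np.asarray(S_from, dtype=np.float64))
    if mu_from.shape != mu_to.shape or S_from.shape != (mu_from.size, mu_from.size):
        raise ValueError("dimension mismatch between means and covariance")
    if not np.allclose(S_from, S_from.T, rtol=1e-8, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    d = mu_from - mu_to
    try:
        sol = np.linalg.solve(S_from, d)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance: using pseudo-inverse", stacklevel=2)
        sol = np.linalg.pinv(S_from) @ d
    q = float(d @ sol)
    return 0.5 * np.sqrt(max(q, 0.0))


def combined_distance(d_ab: float, d_ba: float) -> float:
    """Symmetric pooling ``d_ab*d_ba/(d_ab+d_ba)`` of two directed distances.

    Half the harmonic mean of the two directions; 0/0 (coincident clusters)
    is defined as 0.
    """
    if d_ab < 0 or d_ba < 0:
        raise ValueError("directed distances must be non-negative")
    s = d_ab + d_ba
    if s == 0:
        return 0.0
    return d_ab * d_ba / s


def _pair_combined(stats_a: ClusterStats, stats_b: ClusterStats) -> float:
    return combined_distance(
        half_mahalanobis(stats_a.mu, stats_b.mu, stats_a.S),
        half_mahalanobis(stats_b.mu, stats_a.mu, stats_b.S),
    )


# ---------------------------------------------------------------------------
# the five metrics
# ---------------------------------------------------------------------------

def _rep_stats(cloud: FeatureCloud, label, reg: float) -> dict[int, ClusterStats]:
    mask = np.asarray(cloud.classes).astype(str) == str(label)
    reps = np.asarray(cloud.repetitions)[mask]
    pts = cloud.points[mask]
    return {int(r): cluster_stats(pts[reps == r], reg) for r in np.unique(reps)}


def within_class_distance(cloud: FeatureCloud, label, reg: float = DEFAULT_REG) -> float:
    """WD of one motion: summed combined distances between repetition pairs.

    Sums over all ordered repetition pairs (r, k), r != k; since the combined
    distance is symmetric each unordered pair contributes twice, and the
    degenerate r = k self-terms are 0 by the 0/0 convention.
    """
    stats = _rep_stats(cloud, label, reg)
    reps = sorted(stats)
    if len(reps) < 2:
        raise ValueError(f"class {label!r} needs >= 2 repetitions for WD")
    total = 0.0
    for r in reps:
        for k in reps:
            if r == k:
                continue
            total += _pair_combined(stats[r], stats[k])
    return total


def _class_stats(cloud: FeatureCloud, reg: float) -> dict[str, ClusterStats]:
    return {c: cluster_stats(cloud.points_of(c), reg) for c in cloud.class_order}


def _require_multiclass(stats: dict) -> None:
    if len(stats) < 2:
        raise ValueError("inter-class metrics require at least 2 classes")


def inter_class_nn(cloud: FeatureCloud, reg: float = DEFAULT_REG):
    """IDNN per class (combined distance to the nearest other class) + total."""
    stats = _class_stats(cloud, reg)
    _require_multiclass(stats)
    order = cloud.class_order
    per = {
        j: min(_pair_combined(stats[j], stats[i]) for i in order if i != j)
        for j in order
    }
    return per, float(np.mean(list(per.values())))


def inter_class_all(cloud: FeatureCloud, reg: float = DEFAULT_REG):
    """IDAN per class (summed combined distance to every other class) + total."""
    stats = _class_stats(cloud, reg)
    _require_multiclass(stats)
    order = cloud.class_order
    per = {
        j: sum(_pair_combined(stats[j], stats[i]) for i in order if i != j)
        for j in order
    }
    return per, float(np.mean(list(per.values())))


def _combined_1d(stats_a: ClusterStats, stats_b: ClusterStats, dim: int) -> float:
    gap = abs(stats_a.mu[dim] - stats_b.mu[dim])
    d_ab = 0.5 * gap / np.sqrt(stats_a.S[dim, dim]) if stats_a.S[dim, dim] > 0 else np.inf
    d_ba = 0.5 * gap / np.sqrt(stats_b.S[dim, dim]) if stats_b.S[dim, dim] > 0 else np.inf
    if gap == 0:
        return 0.0
    if np.isinf(d_ab) or np.isinf(d_ba):
        return float(min(d_ab, d_ba))  # harmonic pooling limit as one var -> 0
    return combined_distance(d_ab, d_ba)


def most_separable_dimension(cloud: FeatureCloud, reg: float = DEFAULT_REG):
    """MSD per class + total: nearest neighbor in the best single dimension.

    For each class pair the 1-D combined distance is evaluated per feature
    axis and the most separating axis is kept; each class then takes the
    minimum over the other classes.
    """
    stats = _class_stats(cloud, reg)
    _require_multiclass(stats)
    order = cloud.class_order
    ndim = cloud.n_components

    def best_dim(j, i):
        return max(_combined_1d(stats[j], stats[i], d) for d in range(ndim))

    per = {j: min(best_dim(j, i) for i in order if i != j) for j in order}
    return per, float(np.mean(list(per.values())))


def mean_semi_principal_axis(cloud: FeatureCloud, reg: float = DEFAULT_REG,
                             axis_scale: float = 1.0):
    """MSA per class + total: geometric mean of hyperellipsoid semi-axes.

    Semi-axes are ``axis_scale`` times the square roots of the class
    covariance eigenvalues (1-sigma ellipsoid by default).  Classes with too
    few points for a full-rank covariance are regularized with a warning.
    """
    order = cloud.class_order
    ndim = cloud.n_components
    per = {}
    for j in order:
        pts = cloud.points_of(j)
        use_reg = reg
        if pts.shape[0] <= ndim and reg == 0:
            warnings.warn(
                f"class {j!r} has {pts.shape[0]} points in {ndim}-D; covariance "
                "rank deficient, regularization applied", stacklevel=2,
            )
            use_reg = DEFAULT_REG
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cluster_stats re-warns on rank
            stats = cluster_stats(pts, use_reg)
        axes = axis_scale * stats.axes[:ndim]
        per[j] = float(np.exp(np.mean(np.log(np.clip(axes, 1e-300, None)))))
    return per, float(np.mean(list(per.values())))


# ---------------------------------------------------------------------------
# bundled result
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    """Per-class feature-space metrics plus their across-class means."""

    per_class: pd.DataFrame          # index: class, columns: METRIC_NAMES
    totals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(per_class=self.per_class.to_dict(orient="index"),
                    totals=dict(self.totals))


def compute_metrics(cloud: FeatureCloud, reg: float = DEFAULT_REG,
                    axis_scale: float = 1.0) -> MetricSet:
    """All five cluster metrics of a feature cloud, per class and total."""
    order = cloud.class_order
    wd = {j: within_class_distance(cloud, j, reg) for j in order}
    idnn, idnn_t = inter_class_nn(cloud, reg)
    idan, idan_t = inter_class_all(cloud, reg)
    msd, msd_t = most_separable_dimension(cloud, reg)
    msa, msa_t = mean_semi_principal_axis(cloud, reg, axis_scale)
    per = pd.DataFrame(
        {"WD": wd, "IDNN": idnn, "IDAN": idan, "MSD": msd, "MSA": msa},
        index=order, columns=list(METRIC_NAMES),
    )
    totals = {
        "WD_total": float(np.mean(list(wd.values()))),
        "IDNN_total": idnn_t,
        "IDAN_total": idan_t,
        "MSD_total": msd_t,
        "MSA_total": msa_t,
    }
    return MetricSet(per_class=per, totals=totals)
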