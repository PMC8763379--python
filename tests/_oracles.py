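"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal loops over definitions — per-pair
correlations, explicit matrix inverses, eigendecompositions — so it shares no
code path with the package's vectorized implementations.
"""

import numpy as np
from scipy.stats import pearsonr


# --- classifier ------------------------------------------------------------

def nearest_class_by_mean_correlation(query, frames, labels):
    """Double-loop class-averaged-correlation classifier."""
    classes = sorted(set(labels))
    means = {}
    for c in classes:
        rs = []
        for f, l in zip(frames, labels):
            if l == c:
                rs.append(pearsonr(np.ravel(query), np.ravel(f)).statistic)
        means[c] = float(np.mean(rs))
    best = classes[0]
    for c in classes[1:]:
        if means[c] > means[best]:
            best = c
    return best, means


def loo_predictions(frames, labels):
    """Leave-one-frame-out predictions by the brute-force classifier."""
    preds = []
    for i in range(len(frames)):
        rest_frames = [f for j, f in enumerate(frames) if j != i]
        rest_labels = [l for j, l in enumerate(labels) if j != i]
        preds.append(nearest_class_by_mean_correlation(frames[i], rest_frames, rest_labels)[0])
    return preds


# --- feature-space metrics -------------------------------------------------

def half_md(mu_a, mu_b, S_a):
    d = np.asarray(mu_a) - np.asarray(mu_b)
    return 0.5 * np.sqrt(float(d @ np.linalg.inv(S_a) @ d))


def comb(a, b):
    return 0.0 if (a + b) == 0 else a * b / (a + b)


def _mu_S(pts):
    pts = np.asarray(pts, float)
    return pts.mean(axis=0), np.cov(pts, rowvar=False, ddof=1)


def wd(points_by_rep):
    """Within-class distance: sum over ordered repetition pairs."""
    stats = {r: _mu_S(p) for r, p in points_by_rep.items()}
    total = 0.0
    for r in stats:
        for k in stats:
            if r == k:
                continue
            mu_r, S_r = stats[r]
            mu_k, S_k = stats[k]
            total += comb(half_md(mu_r, mu_k, S_r), half_md(mu_k, mu_r, S_k))
    return total


def _class_pair_comb(stats, j, i):
    mu_j, S_j = stats[j]
    mu_i, S_i = stats[i]
    return comb(half_md(mu_j, mu_i, S_j), half_md(mu_i, mu_j, S_i))


def idnn(points_by_class):
    stats = {c: _mu_S(p) for c, p in points_by_class.items()}
    per = {j: min(_class_pair_comb(stats, j, i) for i in stats if i != j)
           for j in stats}
    return per, float(np.mean(list(per.values())))


def idan(points_by_class):
    stats = {c: _mu_S(p) for c, p in points_by_class.items()}
    per = {j: sum(_class_pair_comb(stats, j, i) for i in stats if i != j)
           for j in stats}
    return per, float(np.mean(list(per.values())))


def msd(points_by_class):
    stats = {c: _mu_S(p) for c, p in points_by_class.items()}
    ndim = len(next(iter(stats.values()))[0])

    def comb_1d(j, i, d):
        mu_j, S_j = stats[j]
        mu_i, S_i = stats[i]
        gap = abs(mu_j[d] - mu_i[d])
        if gap == 0:
            return 0.0
        a = 0.5 * gap / np.sqrt(S_j[d, d])
        b = 0.5 * gap / np.sqrt(S_i[d, d])
        return comb(a, b)

    per = {j: min(max(comb_1d(j, i, d) for d in range(ndim))
                  for i in stats if i != j)
           for j in stats}
    return per, float(np.mean(list(per.values())))


def msa(points_by_class):
    per = {}
    for c, pts in points_by_class.items():
        _, S = _mu_S(pts)
        axes = np.sqrt(np.linalg.eigvalsh(S))
        per[c] = float(np.prod(axes) ** (1.0 / len(axes)))
    return per, float(np.mean(list(per.values())))


# --- PCA -------------------------------------------------------------------

def pca_scores(X, k):
    """Scores from an explicit covariance eigendecomposition."""
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:k]
    return Xc @ vecs[:, order], vals[order]
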