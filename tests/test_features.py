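import numpy as np
import pytest

import _oracles as oracle
from conftest import random_cloud

from smglab import (
    FeatureCloud,
    cluster_stats,
    combined_distance,
    compute_metrics,
    fit_project_pca,
    half_mahalanobis,
    inter_class_all,
    inter_class_nn,
    mean_semi_principal_axis,
    most_separable_dimension,
    within_class_distance,
)


def make_cloud(points, classes, reps):
    ndim = points.shape[1]
    return FeatureCloud(points=np.asarray(points, float),
                        classes=np.asarray(classes),
                        repetitions=np.asarray(reps),
                        mean_=np.zeros(ndim),
                        components_=np.eye(ndim),
                        explained_variance_=np.ones(ndim))


def cloud_with_class_stats(mus, S=None, n=40, seed=0, reps_per_class=2):
    """Cloud whose per-class sample mean/covariance are exactly mus[c] / S."""
    rng = np.random.default_rng(seed)
    ndim = len(mus[0])
    S = np.eye(ndim) if S is None else np.asarray(S, float)
    L = np.linalg.cholesky(S)
    points, classes, reps = [], [], []
    for c, mu in enumerate(mus):
        raw = rng.standard_normal((n, ndim))
        raw -= raw.mean(axis=0)
        C = np.cov(raw, rowvar=False, ddof=1)
        W = np.linalg.inv(np.linalg.cholesky(C))
        white = raw @ W.T          # exactly identity sample covariance
        pts = np.asarray(mu) + white @ L.T
        points.append(pts)
        classes += [f"c{c}"] * n
        reps += list(1 + (np.arange(n) % reps_per_class))
    return make_cloud(np.vstack(points), classes, reps)


class TestPCA:
    def test_lossless_when_data_lies_in_subspace(self):
        rng = np.random.default_rng(0)
        latent = rng.standard_normal((30, 5))
        A = rng.standard_normal((5, 60))
        X = latent @ A + rng.standard_normal(60)  # 5-D affine subspace
        cloud = fit_project_pca((X, ["a"] * 15 + ["b"] * 15, [1] * 30), n_components=5)
        d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        d_proj = np.linalg.norm(cloud.points[:, None] - cloud.points[None, :], axis=-1)
        np.testing.assert_allclose(d_proj, d_orig, atol=1e-8)

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 20)) * np.linspace(5, 0.5, 20)
        cloud = fit_project_pca((X, ["a"] * 40, [1] * 40))
        assert np.all(np.diff(cloud.explained_variance_) <= 1e-12)

    def test_scores_match_eigendecomposition_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 12))
        cloud = fit_project_pca((X, ["a"] * 20, [1] * 20), n_components=5)
        ref, _ = oracle.pca_scores(X, 5)
        for k in range(5):
            col, refcol = cloud.points[:, k], ref[:, k]
            assert (np.allclose(col, refcol, atol=1e-8)
                    or np.allclose(col, -refcol, atol=1e-8))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="components"):
            fit_project_pca((np.zeros((3, 10)), ["a"] * 3, [1] * 3), n_components=5)


class TestElementaryDistances:
    def test_half_mahalanobis_identity(self):
        d = half_mahalanobis([2, 0, 0, 0, 0], [0, 0, 0, 0, 0], np.eye(5))
        assert d == pytest.approx(1.0)

    def test_half_mahalanobis_scales_with_variance(self):
        S = np.diag([4.0, 1, 1, 1, 1])
        d = half_mahalanobis([2, 0, 0, 0, 0], [0, 0, 0, 0, 0], S)
        assert d == pytest.approx(0.5)

    def test_zero_separation(self):
        assert half_mahalanobis([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_asymmetric_covariance_rejected(self):
        S = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            half_mahalanobis([0, 0], [1, 0], S)

    @pytest.mark.parametrize("a,b,want", [
        (1.0, 1.0, 0.5),
        (0.0, 3.0, 0.0),
        (2.0, 3.0, 1.2),
        (0.0, 0.0, 0.0),
    ])
    def test_combined_distance_values(self, a, b, want):
        assert combined_distance(a, b) == pytest.approx(want)

    def test_combined_distance_negative_rejected(self):
        with pytest.raises(ValueError):
            combined_distance(-1.0, 2.0)


class TestWithinClassDistance:
    def test_zero_when_repetition_means_coincide(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((10, 5))
        pts -= pts.mean(axis=0)
        cloud = make_cloud(np.vstack([pts, pts]), ["a"] * 20, [1] * 10 + [2] * 10)
        assert within_class_distance(cloud, "a", reg=0) == pytest.approx(0.0, abs=1e-9)

    def test_two_repetitions_identity_covariance(self):
        # unit mean gap, identity covariances: each direction 0.5, combined
        # 0.25, two ordered pairs -> 0.5
        cloud = cloud_with_class_stats([np.zeros(5)], n=80, seed=4, reps_per_class=1)
        pts = cloud.points
        shifted = pts + np.array([1.0, 0, 0, 0, 0])
        c2 = make_cloud(np.vstack([pts, shifted]), ["a"] * 160, [1] * 80 + [2] * 80)
        assert within_class_distance(c2, "a", reg=0) == pytest.approx(0.5, rel=1e-9)

    def test_single_repetition_rejected(self):
        cloud = make_cloud(np.random.default_rng(0).standard_normal((10, 5)),
                           ["a"] * 10, [1] * 10)
        with pytest.raises(ValueError, match="repetitions"):
            within_class_distance(cloud, "a")


class TestInterClassMetrics:
    def _three_collinear_classes(self):
        mus = [np.zeros(5),
               np.array([2.0, 0, 0, 0, 0]),
               np.array([6.0, 0, 0, 0, 0])]
        return cloud_with_class_stats(mus, n=60, seed=5)

    def test_hand_computed_idnn_idan(self):
        cloud = self._three_collinear_classes()
        per_nn, tot_nn = inter_class_nn(cloud, reg=0)
        assert per_nn["c0"] == pytest.approx(0.5, rel=1e-9)
        assert per_nn["c1"] == pytest.approx(0.5, rel=1e-9)
        assert per_nn["c2"] == pytest.approx(1.0, rel=1e-9)
        assert tot_nn == pytest.approx(2.0 / 3.0, rel=1e-9)
        per_an, tot_an = inter_class_all(cloud, reg=0)
        assert per_an["c0"] == pytest.approx(2.0, rel=1e-9)
        assert per_an["c1"] == pytest.approx(1.5, rel=1e-9)
        assert per_an["c2"] == pytest.approx(2.5, rel=1e-9)
        assert tot_an == pytest.approx(2.0, rel=1e-9)

    def test_coincident_classes_have_zero_idnn(self):
        cloud = cloud_with_class_stats([np.zeros(5), np.zeros(5)], n=40, seed=6)
        per, tot = inter_class_nn(cloud, reg=0)
        assert tot == pytest.approx(0.0, abs=1e-9)

    def test_idnn_never_exceeds_idan(self):
        rng = np.random.default_rng(7)
        pts, classes, reps = random_cloud(rng, n_classes=4)
        cloud = make_cloud(pts, classes, reps)
        per_nn, _ = inter_class_nn(cloud, reg=0)
        per_an, _ = inter_class_all(cloud, reg=0)
        for c in per_nn:
            assert per_nn[c] <= per_an[c] + 1e-12

    def test_single_class_rejected(self):
        cloud = make_cloud(np.random.default_rng(0).standard_normal((10, 5)),
                           ["a"] * 10, [1] * 5 + [2] * 5)
        with pytest.raises(ValueError, match="2 classes"):
            inter_class_nn(cloud)


class TestMostSeparableDimension:
    def test_equals_idnn_for_single_axis_separation(self):
        mus = [np.zeros(5),
               np.array([2.0, 0, 0, 0, 0]),
               np.array([6.0, 0, 0, 0, 0])]
        cloud = cloud_with_class_stats(mus, n=60, seed=8)
        _, tot_msd = most_separable_dimension(cloud, reg=0)
        _, tot_nn = inter_class_nn(cloud, reg=0)
        assert tot_msd == pytest.approx(tot_nn, rel=1e-9)

    def test_coincident_classes_zero(self):
        cloud = cloud_with_class_stats([np.zeros(5), np.zeros(5)], n=40, seed=9)
        _, tot = most_separable_dimension(cloud, reg=0)
        assert tot == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(10)
        pts, classes, reps = random_cloud(rng)
        cloud = make_cloud(pts, classes, reps)
        perm = rng.permutation(pts.shape[1])
        permuted = cloud.replace_points(pts[:, perm])
        _, a = most_separable_dimension(cloud, reg=0)
        _, b = most_separable_dimension(permuted, reg=0)
        assert a == pytest.approx(b, rel=1e-10)


class TestMeanSemiPrincipalAxis:
    def test_spherical_cluster(self):
        cloud = cloud_with_class_stats([np.zeros(5), np.ones(5)],
                                       S=4.0 * np.eye(5), n=50, seed=11)
        per, _ = mean_semi_principal_axis(cloud, reg=0)
        assert per["c0"] == pytest.approx(2.0, rel=1e-9)

    def test_geometric_mean_of_axes(self):
        S = np.diag([1.0, 4.0, 9.0, 16.0, 25.0])
        cloud = cloud_with_class_stats([np.zeros(5), np.ones(5)], S=S, n=50, seed=12)
        per, _ = mean_semi_principal_axis(cloud, reg=0)
        assert per["c0"] == pytest.approx(120.0 ** 0.2, rel=1e-9)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(13)
        pts, classes, reps = random_cloud(rng)
        cloud = make_cloud(pts, classes, reps)
        _, base = mean_semi_principal_axis(cloud, reg=0)
        _, scaled = mean_semi_principal_axis(cloud.replace_points(3.0 * pts), reg=0)
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)

    def test_rank_deficient_class_warns(self):
        pts = np.random.default_rng(14).standard_normal((4, 5))  # 4 pts in 5-D
        cloud = make_cloud(np.vstack([pts, pts + 5]), ["a"] * 4 + ["b"] * 4,
                           [1, 1, 2, 2] * 2)
        with pytest.warns(UserWarning, match="rank"):
            mean_semi_principal_axis(cloud, reg=0)


class TestMetricSet:
    def test_totals_are_means_and_nonnegative(self):
        rng = np.random.default_rng(15)
        pts, classes, reps = random_cloud(rng, n_classes=4, pts_per_rep=10)
        cloud = make_cloud(pts, classes, reps)
        ms = compute_metrics(cloud)
        assert (ms.per_class.values >= 0).all()
        for m in ms.per_class.columns:
            assert ms.totals[f"{m}_total"] == pytest.approx(ms.per_class[m].mean())

    def test_bruteforce_oracle_equivalence(self):
        rng = np.random.default_rng(16)
        for _ in range(15):
            pts, classes, reps = random_cloud(rng)
            cloud = make_cloud(pts, classes, reps)
            by_class = {c: pts[classes == c] for c in np.unique(classes)}
            by_rep = {c: {r: pts[(classes == c) & (reps == r)]
                          for r in np.unique(reps[classes == c])}
                      for c in np.unique(classes)}
            ms = compute_metrics(cloud, reg=0)
            for c in by_class:
                assert ms.per_class.loc[c, "WD"] == pytest.approx(
                    oracle.wd(by_rep[c]), rel=1e-8)
            for name, fn in (("IDNN", oracle.idnn), ("IDAN", oracle.idan),
                             ("MSD", oracle.msd), ("MSA", oracle.msa)):
                per, tot = fn(by_class)
                for c in per:
                    assert ms.per_class.loc[c, name] == pytest.approx(per[c], rel=1e-8)
                assert ms.totals[f"{name}_total"] == pytest.approx(tot, rel=1e-8)

    def test_cluster_stats_axes_sorted_descending(self):
        pts = np.random.default_rng(17).standard_normal((30, 5)) * [5, 4, 3, 2, 1]
        st = cluster_stats(pts, reg=0)
        assert np.all(np.diff(st.axes) <= 0)
        np.testing.assert_allclose(st.S, st.S.T)
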