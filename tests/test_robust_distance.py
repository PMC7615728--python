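"""Tests of classic/MCD/MVE location-scatter estimation and distance flagging."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from growthscreen.robust_distance import (
    LocationScatter,
    _c_step,
    _mcd_consistency,
    _subset_stats,
    classic_estimates,
    default_h,
    distance_flags,
    mahalanobis_sq,
    mcd_estimates,
    mve_estimates,
)


class TestClassicEstimates:
    def test_standardized_data_gives_identity_scatter(self, rng):
        X = rng.standard_normal((4000, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        est = classic_estimates(X)
        np.testing.assert_allclose(est.center, 0, atol=1e-12)
        np.testing.assert_allclose(est.scatter, np.eye(3), atol=0.08)

    def test_duplicate_columns_singular(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        with pytest.raises(np.linalg.LinAlgError):
            classic_estimates(X)

    def test_hand_computed_mean_and_covariance(self):
        X = np.array(
            [[1, 2, 0], [3, 5, 1], [5, 6, 0], [7, 9, 1], [9, 10, 3]], dtype=float
        )
        est = classic_estimates(X)
        # independent arithmetic: means and (n-1)-denominator cross products
        means = [sum(X[:, j]) / 5 for j in range(3)]
        np.testing.assert_allclose(est.center, means)
        for j in range(3):
            for k in range(3):
                s = sum((X[i, j] - means[j]) * (X[i, k] - means[k]) for i in range(5)) / 4
                assert est.scatter[j, k] == pytest.approx(s)


class TestMahalanobis:
    def test_zero_at_center(self):
        est = LocationScatter([1.0, 2.0, 3.0], np.eye(3), "classic")
        assert mahalanobis_sq([[1.0, 2.0, 3.0]], est)[0] == pytest.approx(0.0)

    def test_identity_scatter_is_euclidean(self, rng):
        est = LocationScatter(np.zeros(3), np.eye(3), "classic")
        X = rng.normal(size=(20, 3))
        np.testing.assert_allclose(mahalanobis_sq(X, est), (X**2).sum(axis=1))

    def test_diagonal_hand_example(self):
        est = LocationScatter(np.zeros(3), np.diag([1.0, 4.0, 9.0]), "classic")
        # 1/1 + 4/4 + 9/9
        assert mahalanobis_sq([[1.0, 2.0, 3.0]], est)[0] == pytest.approx(3.0)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(50, 3))
        est = classic_estimates(X)
        A = np.array([[2.0, 0.3, 0.0], [0.1, 1.5, 0.2], [0.0, 0.4, 0.8]])
        b = np.array([1.0, -2.0, 3.0])
        est_t = LocationScatter(A @ est.center + b, A @ est.scatter @ A.T, "classic")
        np.testing.assert_allclose(
            mahalanobis_sq(X @ A.T + b, est_t), mahalanobis_sq(X, est), rtol=1e-8
        )

    def test_mean_distance_near_dimension(self, rng):
        X = rng.standard_normal((5000, 3))
        d2 = mahalanobis_sq(X, classic_estimates(X))
        assert d2.mean() == pytest.approx(3.0, abs=0.01)


class TestDistanceFlags:
    def test_chi_square_threshold_from_table(self):
        res = distance_flags(np.array([0.0]))
        # 0.99 quantile of chi-square with 3 df from a standard table
        assert res.threshold == pytest.approx(11.345, abs=5e-4)

    def test_strict_boundary(self):
        res = distance_flags(np.array([11.3, 11.4, 0.0]))
        np.testing.assert_array_equal(res.flags, [False, True, False])

    def test_null_flag_rate_about_one_percent(self, rng):
        X = rng.standard_normal((5000, 3))
        res = distance_flags(mahalanobis_sq(X, classic_estimates(X)))
        assert 0.005 < res.flags.mean() < 0.016

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_flags(np.array([-1.0]))


def _contaminated_sample(rng, n=500, frac=0.10, shift=20.0):
    X = rng.standard_normal((n, 3))
    k = int(frac * n)
    X[:k] += shift
    return X, k


class TestMcd:
    def test_center_close_to_truth_on_clean_data(self, rng):
        X = rng.standard_normal((500, 3))
        est = mcd_estimates(X, seed=1)
        assert np.abs(est.center).max() < 3 / np.sqrt(500) * 3

    def test_robust_to_gross_contamination(self, rng):
        X, _ = _contaminated_sample(rng)
        est = mcd_estimates(X, seed=2)
        classic = classic_estimates(X)
        assert np.linalg.norm(est.center) < 0.5
        assert np.linalg.norm(classic.center) > 1.0

    def test_seed_determinism(self, rng):
        X, _ = _contaminated_sample(rng)
        a = mcd_estimates(X, seed=3)
        b = mcd_estimates(X, seed=3)
        np.testing.assert_array_equal(a.center, b.center)
        np.testing.assert_array_equal(a.scatter, b.scatter)

    def test_c_steps_never_increase_determinant(self, rng):
        X, _ = _contaminated_sample(rng, n=200)
        h = default_h(200, 3)
        idx = rng.choice(200, size=4, replace=False)
        center, scatter = _subset_stats(X, idx)
        dets = []
        for _ in range(10):
            keep = _c_step(X, center, scatter, h)
            center, scatter = _subset_stats(X, keep)
            dets.append(np.linalg.det(scatter))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(dets, dets[1:]))

    def test_matches_exhaustive_subset_enumeration(self, rng):
        X = rng.normal(size=(10, 2))
        X[0] += 8.0  # one planted outlier
        h = 7
        best_det, best_sub = np.inf, None
        for sub in combinations(range(10), h):
            det = np.linalg.det(np.cov(X[list(sub)], rowvar=False, ddof=1))
            if det < best_det:
                best_det, best_sub = det, sub
        est = mcd_estimates(X, h=h, n_trials=500, seed=4)
        factor = _mcd_consistency(10, 2, h)
        np.testing.assert_allclose(est.center, X[list(best_sub)].mean(axis=0), rtol=1e-8)
        assert np.linalg.det(est.scatter) == pytest.approx(best_det * factor**2, rel=1e-6)

    def test_exact_fit_detected(self):
        X = np.zeros((40, 3))
        X[:, 0] = np.arange(40)
        X[:5] += np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(np.linalg.LinAlgError):
            mcd_estimates(X, seed=0)

    def test_agrees_with_sklearn_mincovdet(self, rng):
        from sklearn.covariance import MinCovDet

        X, _ = _contaminated_sample(rng)
        est = mcd_estimates(X, seed=5)
        sk = MinCovDet(support_fraction=est.h / len(X), random_state=0).fit(X)
        # both should locate the clean majority (true center 0)
        assert np.linalg.norm(est.center - sk.location_) < 0.3
        d_mine = mahalanobis_sq(X, est)
        order_agreement = np.corrcoef(np.argsort(np.argsort(d_mine)),
                                      np.argsort(np.argsort(sk.mahalanobis(X))))[0, 1]
        # sklearn reweights its covariance, so ranks agree closely but not exactly
        assert order_agreement > 0.95

    def test_invalid_h(self, rng):
        with pytest.raises(ValueError):
            mcd_estimates(rng.normal(size=(20, 3)), h=5, seed=0)


class TestMve:
    def test_robust_to_gross_contamination(self, rng):
        X, _ = _contaminated_sample(rng)
        est = mve_estimates(X, seed=2)
        assert np.linalg.norm(est.center) < 0.6

    def test_seed_determinism(self, rng):
        X, _ = _contaminated_sample(rng)
        a = mve_estimates(X, seed=3)
        b = mve_estimates(X, seed=3)
        np.testing.assert_array_equal(a.center, b.center)
        np.testing.assert_array_equal(a.scatter, b.scatter)

    def test_matches_exhaustive_subset_enumeration(self, rng):
        X = rng.normal(size=(12, 2))
        X[:2] += 6.0
        h = 10
        p = 2
        best = np.inf
        for sub in combinations(range(12), p + 1):
            center, shape = X[list(sub)].mean(0), np.cov(X[list(sub)], rowvar=False, ddof=1)
            det = np.linalg.det(shape)
            if det <= 1e-12:
                continue
            d2 = mahalanobis_sq(X, LocationScatter(center, shape, "tmp"))
            m2h = np.partition(d2, h - 1)[h - 1]
            best = min(best, det * m2h**p)
        est = mve_estimates(X, h=h, n_trials=4000, seed=6)
        vol2 = np.linalg.det(est.scatter) * stats.chi2.ppf(0.5, p) ** p
        assert vol2 == pytest.approx(best, rel=1e-8)

    def test_planted_outliers_flagged(self, rng):
        X = rng.normal(size=(12, 2))
        X[:2] += 8.0
        est = mve_estimates(X, h=10, n_trials=2000, seed=7)
        flags = distance_flags(mahalanobis_sq(X, est), df=2).flags
        assert flags[0] and flags[1]
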