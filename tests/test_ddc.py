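"""Tests of the DetectDeviatingCells steps and the composed pipeline."""

import numpy as np
import pytest

from growthscreen.ddc import (
    DDCParams,
    ddc_correlations,
    ddc_fit,
    ddc_flag_cells,
    ddc_flag_rows,
    ddc_predict,
    ddc_standardize,
)
from growthscreen.univariate import robust_sds


def _correlated_data(rng, n=400, rho=0.85, p=3):
    cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
    return rng.multivariate_normal(np.zeros(p), cov, size=n)


class TestParams:
    def test_cutoff_derived_from_tol_prob(self):
        # sqrt of the 0.99 quantile of chi-square(1) = 2.5758...
        assert DDCParams().c == pytest.approx(2.5758, abs=1e-4)
        assert DDCParams(tol_prob=0.95).c == pytest.approx(1.9600, abs=1e-4)

    def test_validation(self):
        with pytest.raises(ValueError):
            DDCParams(corrlim=1.5)
        with pytest.raises(ValueError):
            DDCParams(tol_prob=0.0)


class TestStandardize:
    def test_deviant_cell_set_aside(self, rng):
        X = np.column_stack([rng.normal(size=50), rng.normal(size=50)])
        X[7, 0] = 50.0
        z, aside = ddc_standardize(X)
        assert aside[7, 0]
        assert aside.sum() <= 3

    def test_matches_robust_sds(self, rng):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        X = np.column_stack([x, rng.normal(size=5)])
        z, _ = ddc_standardize(X)
        np.testing.assert_allclose(z[:, 0], robust_sds(x))

    def test_affine_equivariance(self, rng):
        X = rng.normal(size=(60, 2))
        z1, a1 = ddc_standardize(X)
        X2 = X.copy()
        X2[:, 0] = 3.5 * X2[:, 0] - 11.0
        z2, a2 = ddc_standardize(X2)
        np.testing.assert_allclose(z1, z2, atol=1e-9)
        np.testing.assert_array_equal(a1, a2)

    def test_zero_mad_column_rejected(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        with pytest.raises(ValueError, match="MAD"):
            ddc_standardize(X)


class TestCorrelations:
    def test_exact_linear_dependence(self, rng):
        x = rng.normal(size=100)
        z, aside = ddc_standardize(np.column_stack([x, 2 * x]))
        corr, connected = ddc_correlations(z, aside)
        assert corr[0, 1] == pytest.approx(1.0)
        assert connected == [[1], [0]]

    def test_independent_columns_stay_disconnected(self, rng):
        z, aside = ddc_standardize(rng.normal(size=(1000, 2)))
        corr, connected = ddc_correlations(z, aside)
        assert abs(corr[0, 1]) < 0.1
        assert connected == [[], []]

    def test_outlier_trimmed_from_correlation(self, rng):
        x = rng.normal(size=200)
        y = x.copy()
        y[0] = 60.0  # gross cell error
        z, aside = ddc_standardize(np.column_stack([x, y]))
        corr, _ = ddc_correlations(z, aside)
        assert corr[0, 1] > 0.99


class TestPredict:
    def test_exact_dependence_predicts_observation(self, rng):
        x = rng.normal(size=80)
        z, aside = ddc_standardize(np.column_stack([x, 3 * x + 2]))
        corr, connected = ddc_correlations(z, aside)
        pred = ddc_predict(z, corr, aside=aside, connected=connected)
        clean = ~aside.any(axis=1)
        np.testing.assert_allclose(pred[clean], z[clean], atol=1e-9)

    def test_standalone_column_predicts_median(self, rng):
        z, aside = ddc_standardize(rng.normal(size=(500, 2)))
        corr, connected = ddc_correlations(z, aside)
        pred = ddc_predict(z, corr, aside=aside, connected=connected)
        np.testing.assert_array_equal(pred, 0.0)

    def test_hand_computed_slope_and_weighting(self):
        # single connected pair: prediction = deshrunk median-of-ratios slope
        z = np.array([[1.0, 2.0], [2.0, 3.8], [-1.0, -2.2], [0.5, 1.0]])
        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        aside = np.zeros_like(z, dtype=bool)
        pred = ddc_predict(z, corr, aside=aside, connected=[[1], [0]])
        # centers: m0 = median(z0) = 0.75, m1 = median(z1) = 1.5
        # b_01 = median((z0-.75)/(z1-1.5)) = median(.5, .5435, .4730, .5) = .5
        raw0 = 0.75 + 0.5 * (z[:, 1] - 1.5)
        # deshrinkage: median(z0/raw0) = median(1, 1.0526, .9091, 1) = 1
        np.testing.assert_allclose(pred[:, 0], raw0, rtol=1e-12)
        # b_10 = median((z1-1.5)/(z0-.75)) = median(2, 1.84, 2.1143, 2) = 2
        np.testing.assert_allclose(pred[:, 1], 1.5 + 2.0 * (z[:, 0] - 0.75), rtol=1e-12)


class TestFlagging:
    def test_corrupted_cell_flagged_clean_cells_not(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x, -x])
        X[13, 1] = 40.0
        fit = ddc_fit(X)
        assert fit.cell_flags[13, 1]
        assert fit.cell_flags.sum() == 1

    def test_prediction_equal_observation_no_flags(self, rng):
        z = rng.normal(size=(50, 2))
        residual, flags = ddc_flag_cells(z, z.copy())
        assert not flags.any()
        np.testing.assert_array_equal(residual, 0.0)

    def test_null_cell_flag_rate_near_nominal(self, rng):
        X = _correlated_data(rng, n=2000)
        fit = ddc_fit(X)
        assert 0.003 < fit.cell_flags.mean() < 0.03

    def test_row_with_zero_residuals_unflagged(self):
        residual = np.zeros((20, 3))
        residual[1] = [5.0, -6.0, 7.0]
        T, flags = ddc_flag_rows(residual)
        assert T[0] == pytest.approx(0.0)
        assert flags[1] and not flags[0]

    def test_grossly_corrupted_row_flagged(self, rng):
        X = _correlated_data(rng, n=300)
        X[7] = [90.0, -80.0, 70.0]
        fit = ddc_fit(X)
        assert fit.row_flags[7]
        assert fit.row_stat[7] > 0.99


class TestFit:
    def test_growth_like_corruption(self, cohort):
        X = np.column_stack(
            [cohort["age_months"], cohort["height_cm"].astype(float), cohort["log_weight"]]
        )
        X[11, 1] = 15.0  # a skipped-digit height
        fit = ddc_fit(X)
        assert fit.cell_flags[11, 1]

    def test_deterministic(self, rng):
        X = _correlated_data(rng, n=200)
        a, b = ddc_fit(X), ddc_fit(X)
        np.testing.assert_array_equal(a.residual, b.residual)
        np.testing.assert_array_equal(a.cell_flags, b.cell_flags)

    def test_column_affine_equivariance_of_flags(self, rng):
        X = _correlated_data(rng, n=300)
        X[5, 0] += 30
        X2 = X.copy()
        X2[:, 2] = 0.25 * X2[:, 2] + 7.0
        np.testing.assert_array_equal(ddc_fit(X).cell_flags, ddc_fit(X2).cell_flags)

    def test_exact_dependence_perfect_precision_recall(self, rng):
        x = rng.normal(size=500)
        X = np.column_stack([x, 1.5 * x, x - 2])
        corrupted = [(3, 0), (77, 1), (200, 2), (404, 1)]
        for i, j in corrupted:
            X[i, j] += 25.0
        flags = ddc_fit(X).cell_flags
        assert flags.sum() == len(corrupted)
        assert all(flags[i, j] for i, j in corrupted)

    def test_residual_is_valid_roc_score(self, rng):
        X = _correlated_data(rng, n=300)
        X[3, 1] += 30
        fit = ddc_fit(X)
        sweep = np.abs(fit.residual[:, 1]) > fit.params.c
        np.testing.assert_array_equal(sweep, fit.cell_flags[:, 1])

    def test_predicted_values_in_data_units(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([10 * x + 100, 5 * x + 50])
        fit = ddc_fit(X)
        clean = ~(np.abs(fit.z) > fit.params.c).any(axis=1)
        np.testing.assert_allclose(fit.predicted[clean, 0], X[clean, 0], rtol=1e-6)
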