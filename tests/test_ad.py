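"""Leverage, Williams classification and within/outside-domain evaluation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarscreen.ad import (
    ADReport,
    LeverageAD,
    ad_evaluation,
    ad_report,
    leverage,
    leverage_threshold,
    standardized_cv_residuals,
    williams_classify,
)
from qsarscreen.models import KNeighborsActivityRegressor


class TestLeverage:
    def test_simple_regression_closed_form(self):
        # h_i = 1/n + (x_i - x̄)² / Σ(x - x̄)² for one feature plus intercept
        h = leverage(np.array([[-1.0], [0.0], [1.0]]))
        np.testing.assert_allclose(h, [5 / 6, 1 / 3, 5 / 6], atol=1e-12)

    def test_identical_rows_equal_leverage(self):
        h = leverage(np.ones((6, 3)))
        np.testing.assert_allclose(h, h[0])

    def test_trace_equals_rank(self, rng):
        X = rng.normal(size=(50, 5))
        assert leverage(X).sum() == pytest.approx(6.0, abs=1e-8)

    def test_rank_deficient_design(self, rng):
        x = rng.normal(size=(30, 1))
        X = np.hstack([x, 2.0 * x, x - 1.0])  # rank 1 + intercept
        h = leverage(X)
        assert h.sum() == pytest.approx(2.0, abs=1e-8)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=5, max_value=60), st.integers(min_value=1, max_value=8),
           st.integers(min_value=0, max_value=999))
    def test_bounds_and_trace_property(self, n, p, seed):
        X = np.random.default_rng(seed).normal(size=(n, p))
        h = leverage(X)
        assert (h >= -1e-12).all() and (h <= 1 + 1e-12).all()
        assert h.sum() == pytest.approx(min(n, p + 1), abs=1e-6)


class TestThreshold:
    def test_study_scale_value(self):
        assert leverage_threshold(301, 1647) == pytest.approx(0.5483, abs=5e-5)

    def test_degenerate_case(self):
        assert leverage_threshold(1, 3) == pytest.approx(1.0)

    def test_alternative_multiplier(self):
        assert leverage_threshold(301, 1647, multiplier=2.0) == pytest.approx(0.3655, abs=5e-5)


class TestResiduals:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero residual variance"):
            res = standardized_cv_residuals(y, y)
        np.testing.assert_array_equal(res, np.zeros(3))

    def test_unit_sd_case(self):
        res = standardized_cv_residuals(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(res, [-1.0, 0.0, 1.0])

    def test_planted_label_corruption_flagged(self, rng):
        X = rng.normal(size=(120, 4))
        y = X.sum(axis=1)
        y_corrupt = y.copy()
        y_corrupt[17] += 6.0
        from qsarscreen.models import cv_predictions

        yhat = cv_predictions(KNeighborsActivityRegressor(), X, y_corrupt, k=10, seed=0)
        res = standardized_cv_residuals(y_corrupt, yhat)
        assert abs(res[17]) > 2.5


class TestWilliamsClassify:
    def test_boundary_points_stay_in_domain(self):
        report = williams_classify(h=[0.3, 0.1], res=[2.5, 0.0], h_star=0.3)
        assert list(report.classes) == ["in_domain", "in_domain"]

    def test_all_quiet_all_in_domain(self):
        report = williams_classify(h=np.full(5, 0.05), res=np.zeros(5), h_star=0.2)
        assert report.in_domain.all()

    def test_class_quadrants(self):
        report = williams_classify(
            h=[0.5, 0.1, 0.5, 0.1], res=[0.0, 3.0, -3.0, 0.0], h_star=0.3
        )
        assert list(report.classes) == ["X_outlier", "Y_outlier", "XY_outlier", "in_domain"]


def _planted_ad_dataset(seed=0):
    """Inliers + a far-field X-outlier cluster + corrupted labels.

    The X-outliers form a tight cluster far outside the feature cloud with
    unremarkable labels (the inlier mean), so they carry extreme leverage but
    ordinary residuals — the case only leverage can flag. The Y-outliers sit
    inside the cloud, mutually well separated, with labels shifted by many
    response SDs."""
    rng = np.random.default_rng(seed)
    n_in, n_x, n_y = 150, 5, 6
    X_in = rng.normal(size=(n_in, 6))
    X_out = rng.normal(size=(n_x, 6)) + 20.0
    X = np.vstack([X_in, X_out])
    beta = 0.5 * rng.normal(size=6)
    y = X @ beta
    y[n_in:] = y[:n_in].mean()
    y_idx = []
    for c in rng.permutation(n_in):
        if all(np.linalg.norm(X_in[c] - X_in[j]) > 3.0 for j in y_idx):
            y_idx.append(c)
        if len(y_idx) == n_y:
            break
    y_idx = np.array(y_idx)
    y[y_idx] += 8.0 * np.sign(rng.normal(size=len(y_idx)))
    x_idx = np.arange(n_in, n_in + n_x)
    clean = np.setdiff1d(np.arange(len(X)), np.concatenate([x_idx, y_idx]))
    return X, y, x_idx, y_idx, clean


class TestPlantedOutliers:
    def test_exact_sensitivity_and_specificity_at_zero_noise(self):
        X, y, x_idx, y_idx, clean = _planted_ad_dataset(seed=0)
        report = ad_report(KNeighborsActivityRegressor(), X, y, k=10, seed=0)
        # every planted X-outlier exceeds the leverage threshold and, having
        # an unremarkable label, is classed as a pure X outlier
        assert (report.h[x_idx] > report.h_star).all()
        assert (report.classes[x_idx] == "X_outlier").all()
        # every planted label corruption exceeds the residual cut
        assert (np.abs(report.res[y_idx]) > report.res_cut).all()
        # no clean compound is flagged at all
        assert (report.classes[clean] == "in_domain").all()


class TestADEvaluation:
    def test_no_outliers_outside_metrics_absent(self, rng):
        X = rng.normal(size=(80, 3))
        y = X.sum(axis=1) + rng.normal(0, 0.1, 80)
        report = ad_report(KNeighborsActivityRegressor(), X, y, k=8, seed=0)
        if not report.in_domain.all():  # force an all-inside report
            report.classes[:] = "in_domain"
        evaluation = ad_evaluation(KNeighborsActivityRegressor(), X, y, report, k=8, seed=0)
        assert evaluation.outside is None

    def test_distribution_shift_degrades_outside_error(self):
        """Train-inside/test-outside error exceeds inside-domain CV error in
        at least 80% of seeds (statistical assertion over 20 seeds)."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X_in = rng.normal(size=(100, 4))
            X_out = rng.normal(size=(8, 4)) * 6.0 + 12.0
            X = np.vstack([X_in, X_out])
            beta = rng.normal(size=4)
            y = X @ beta + rng.normal(0, 0.2, len(X))
            report = ad_report(KNeighborsActivityRegressor(), X, y, k=10, seed=seed)
            evaluation = ad_evaluation(KNeighborsActivityRegressor(), X, y, report, k=10, seed=seed)
            if evaluation.outside is None:
                continue
            if evaluation.outside["rmse"] > evaluation.inside.mean["rmse"]:
                wins += 1
        assert wins >= 16

    def test_reproducible_run_to_run(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        a = ad_report(KNeighborsActivityRegressor(), X, y, k=6, seed=9)
        b = ad_report(KNeighborsActivityRegressor(), X, y, k=6, seed=9)
        np.testing.assert_array_equal(a.res, b.res)
        np.testing.assert_array_equal(a.classes, b.classes)


class TestLeverageADEstimator:
    def test_fit_predict_surface(self, rng):
        X = rng.normal(size=(50, 3))
        y = X.sum(axis=1)
        est = LeverageAD(k=5, seed=0).fit(X, y)
        classes = est.predict()
        assert len(classes) == 50
        assert est.report_.P == 4
        assert est.get_params()["k"] == 5
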