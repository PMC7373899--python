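"""Likelihood machinery: prior, objective, multistart, profiles, BIC."""

import numpy as np
import pytest

from ifnstat.estimation import (FitResult, LeastSquaresObjective, bic,
                                chi2_delta, compare_models, l2_prior,
                                multistart, prediction_profile, profile,
                                waterfall_groups)


def test_l2_prior_values():
    assert l2_prior([5.0]) == pytest.approx(1.0)       # theta = 1e5
    assert l2_prior([0.0]) == pytest.approx(0.0)       # theta = 1
    assert l2_prior([-5.0]) == pytest.approx(1.0)      # theta = 1e-5
    assert l2_prior([1.0, -2.0]) == pytest.approx((1 + 4) / 25)


def _linear_objective(X, y, sigma=1.0, prior=False):
    def resid(b):
        return (y - X @ b) / sigma
    return LeastSquaresObjective(resid, X.shape[1], prior=prior,
                                 jac=lambda b: -X / sigma)


def test_objective_self_consistency_and_quadratic_residual():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    beta = np.array([0.5, -0.3])
    y = X @ beta
    obj = _linear_objective(X, y, prior=True)
    assert obj.data_value(beta) == pytest.approx(0.0, abs=1e-24)
    assert obj.value(beta) == pytest.approx(l2_prior(beta))
    # a k-sigma offset on one point raises the objective by k^2
    y2 = y.copy()
    y2[0] += 3.0
    obj2 = _linear_objective(X, y2, prior=False)
    assert obj2.value(beta) == pytest.approx(9.0)


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    obj = _linear_objective(X, y, sigma=0.7, prior=True)
    x = rng.normal(size=3)
    g = obj.gradient(x)
    for _ in range(10):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        h = 1e-6
        fd = (obj.value(x + h * d) - obj.value(x - h * d)) / (2 * h)
        assert fd == pytest.approx(float(g @ d), rel=1e-4)


def test_multistart_convex_quadratic():
    X = np.array([[2.0, 0.3], [0.1, 1.5], [1.0, 1.0], [0.5, -0.5]])
    beta = np.array([1.2, -0.4])
    obj = _linear_objective(X, X @ beta, prior=False)
    results = multistart(obj, n_starts=8, start_box=(-4, 4), seed=1)
    vals = [r.value for r in results]
    assert vals == sorted(vals)
    for r in results:
        assert np.allclose(r.x, beta, atol=1e-6)
    assert len(waterfall_groups(results)) == 1


def test_multistart_requires_starts():
    obj = _linear_objective(np.eye(2), np.zeros(2), prior=False)
    with pytest.raises(ValueError):
        multistart(obj, n_starts=0)


def test_profile_matches_analytic_parabola():
    """Linear-Gaussian model: the profile is the exact quadratic and the CI
    endpoints match the Wald interval from the covariance matrix."""
    rng = np.random.default_rng(11)
    X = rng.normal(size=(30, 2))
    beta = np.array([0.8, -0.5])
    sigma = 0.5
    y = X @ beta + rng.normal(0, sigma, 30)
    obj = _linear_objective(X, y, sigma=sigma, prior=False)
    best_x, best_val, _ = np.linalg.lstsq(X, y, rcond=None)[0], None, None
    best_val = obj.value(best_x)
    fit = FitResult(x=best_x, value=best_val, success=True, start_index=0,
                    n_free=2)
    cov = sigma ** 2 * np.linalg.inv(X.T @ X)
    for idx in (0, 1):
        prof = profile(obj, fit, idx, level=0.95, step0=0.02)
        assert prof.classification == "identifiable"
        se = np.sqrt(cov[idx, idx])
        half = np.sqrt(chi2_delta(0.95)) * se
        assert prof.ci[0] == pytest.approx(best_x[idx] - half, rel=0.01)
        assert prof.ci[1] == pytest.approx(best_x[idx] + half, rel=0.01)
        assert prof.objective.min() >= best_val - 1e-9


def test_structurally_absent_parameter_is_flat():
    X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
    y = np.array([1.0, 1.1, 0.9])
    obj = _linear_objective(X, y, prior=False)
    best = np.array([1.0, 0.3])
    fit = FitResult(x=best, value=obj.value(best), success=True,
                    start_index=0, n_free=2)
    prof = profile(obj, fit, 1, level=0.95)
    assert prof.classification == "open_both"
    assert np.ptp(prof.objective) < 1e-9


def test_sum_of_rates_identifiable_components_open():
    """Only the sum 10^a + 10^b is observed: each log-rate is open to
    minus infinity but bounded above; the sum itself is identifiable."""
    total = 2.0

    def resid(x):
        return np.array([(10.0 ** x[0] + 10.0 ** x[1] - total) / 0.05])

    obj = LeastSquaresObjective(resid, 2, prior=False)
    best = np.array([0.0, 0.0])  # 1 + 1 = 2
    fit = FitResult(x=best, value=obj.value(best), success=True,
                    start_index=0, n_free=2)
    prof = profile(obj, fit, 0, level=0.95, box_decades=4.0)
    assert prof.classification == "open_left"
    assert np.isnan(prof.ci[0]) and np.isfinite(prof.ci[1])

    def resid_sum(x):  # reparameterized: s = log10 of the sum
        return np.array([(10.0 ** x[0] - total) / 0.05])

    obj_s = LeastSquaresObjective(resid_sum, 1, prior=False)
    fit_s = FitResult(x=np.array([np.log10(total)]),
                      value=0.0, success=True, start_index=0, n_free=1)
    prof_s = profile(obj_s, fit_s, 0, level=0.95)
    assert prof_s.classification == "identifiable"


def test_prediction_profile_linear_oracle():
    """Prediction interval for x0^T beta matches the analytic prediction
    variance of the linear-Gaussian model."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 2))
    beta = np.array([0.6, 1.1])
    sigma = 0.4
    y = X @ beta + rng.normal(0, sigma, 40)
    obj = _linear_objective(X, y, sigma=sigma, prior=False)
    bhat = np.linalg.lstsq(X, y, rcond=None)[0]
    fit = FitResult(x=bhat, value=obj.value(bhat), success=True,
                    start_index=0, n_free=2)
    x0 = np.array([1.0, -2.0])
    lo, hi = prediction_profile(obj, fit, lambda b: float(x0 @ b),
                                level=0.68)
    pred = float(x0 @ bhat)
    assert lo <= pred <= hi
    cov = sigma ** 2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(x0 @ cov @ x0)
    half = np.sqrt(chi2_delta(0.68)) * se
    assert hi - lo == pytest.approx(2 * half, rel=0.05)
    # zero-noise data: the interval collapses onto the point prediction
    obj0 = _linear_objective(X, X @ beta, sigma=1e-3, prior=False)
    fit0 = FitResult(x=beta, value=0.0, success=True, start_index=0,
                     n_free=2)
    lo0, hi0 = prediction_profile(obj0, fit0, lambda b: float(x0 @ b),
                                  level=0.68)
    assert hi0 - lo0 < 0.05 * max(abs(float(x0 @ beta)), 1.0)


def test_bic_formula_and_monotonicity():
    assert bic(100.0, 12, 100) - bic(100.0, 10, 100) == pytest.approx(
        2 * np.log(100))
    fits = {"small": FitResult(np.zeros(1), 100.0, True, 0, n_free=10),
            "big": FitResult(np.zeros(1), 100.0, True, 0, n_free=12)}
    ranking = compare_models(fits, n_data=100)
    assert ranking.iloc[0]["variant"] == "small"
    assert ranking.iloc[1]["delta_bic"] == pytest.approx(2 * np.log(100))
    # an extra parameter that cannot reduce the objective never lowers BIC
    assert bic(100.0, 11, 100) > bic(100.0, 10, 100)
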