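"""Coordinate-descent solver: closed forms, oracles, KKT, and LOOCV."""

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from kinresp import (
    SolverConfig,
    fit_elastic_net,
    kkt_violation,
    loocv,
    objective,
    predict,
    predict_viability,
)


def objective_reference(X, y, beta0, beta, alpha, rho):
    """Independent transcription of the penalized least-squares objective."""
    m = len(y)
    resid = y - beta0 - X @ beta
    return (
        np.sum(resid**2) / (2 * m)
        + alpha * rho * np.sum(np.abs(beta))
        + 0.5 * alpha * (1 - rho) * np.sum(beta**2)
    )


def lbfgs_oracle(X, y, alpha, rho):
    """Convex-minimizer oracle: split beta = b+ - b- to smooth the L1 term."""
    m, p = X.shape

    def f(z):
        beta0, bp, bm = z[0], z[1 : p + 1], z[p + 1 :]
        beta = bp - bm
        resid = y - beta0 - X @ beta
        return (
            np.sum(resid**2) / (2 * m)
            + alpha * rho * np.sum(bp + bm)
            + 0.5 * alpha * (1 - rho) * np.sum(beta**2)
        )

    z0 = np.zeros(2 * p + 1)
    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = minimize(f, z0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    beta = res.x[1 : p + 1] - res.x[p + 1 :]
    return res.x[0], beta


@dataclass
class XY:
    """Bare (X, y) container accepted by the solver."""

    X: np.ndarray
    y: np.ndarray


TIGHT = dict(tol=1e-12, max_sweeps=200_000)


class TestObjective:
    def test_centered_constant_model(self):
        y = np.array([1.0, 2.0, 4.0])
        d = XY(np.zeros((3, 2)), y)
        cfg = SolverConfig(alpha=0.3, rho=0.5)
        expected = np.sum((y - y.mean()) ** 2) / 6
        assert objective(d, y.mean(), np.zeros(2), cfg) == pytest.approx(expected)

    def test_penalty_vanishes_at_alpha_zero(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(5, 3)), rng.normal(size=5)
        beta = rng.normal(size=3)
        d = XY(X, y)
        half_mse = np.mean((y - 1.5 - X @ beta) ** 2) / 2
        assert objective(d, 1.5, beta, SolverConfig(alpha=0.0)) == pytest.approx(half_mse)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(7, 4)), rng.normal(size=7)
        beta, beta0 = rng.normal(size=4), 0.3
        cfg = SolverConfig(alpha=0.2, rho=0.4)
        assert objective(XY(X, y), beta0, beta, cfg) == pytest.approx(
            objective_reference(X, y, beta0, beta, 0.2, 0.4), abs=1e-12
        )


class TestFit:
    def test_ols_interpolating_line(self):
        d = XY(np.array([[1.0], [2.0]]), np.array([1.0, 2.0]))
        fit = fit_elastic_net(d, SolverConfig(alpha=0.0, **TIGHT))
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_coordinate_closed_form(self):
        # centered +/-1 design: soft-threshold solution in one step
        d = XY(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
        fit = fit_elastic_net(d, SolverConfig(alpha=0.15, rho=0.01, **TIGHT))
        expected = (1.0 - 0.15 * 0.01) / (1.0 + 0.15 * 0.99)
        assert fit.coefficients[0] == pytest.approx(expected, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_convex_minimizer_oracle(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(10, 5)), rng.normal(size=10)
        cfg = SolverConfig(alpha=0.15, rho=0.01, **TIGHT)
        fit = fit_elastic_net(XY(X, y), cfg)
        b0_o, beta_o = lbfgs_oracle(X, y, 0.15, 0.01)
        f_cd = objective_reference(X, y, fit.intercept, fit.coefficients, 0.15, 0.01)
        f_or = objective_reference(X, y, b0_o, beta_o, 0.15, 0.01)
        assert f_cd <= f_or + 1e-8

    def test_objective_non_increasing_across_sweeps(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 6))
        X[:, 3] = X[:, 2] + 0.01 * rng.normal(size=12)  # correlated columns
        y = rng.normal(size=12)
        cfg0 = SolverConfig(alpha=0.05, rho=0.3)
        vals = []
        for k in range(1, 16):
            cfg = SolverConfig(alpha=0.05, rho=0.3, max_sweeps=k, tol=1e-15)
            fit = fit_elastic_net(XY(X, y), cfg)
            vals.append(objective(XY(X, y), fit.intercept, fit.coefficients, cfg0))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_kkt_certificate_zero_and_active_coordinates(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(20, 30)), rng.normal(size=20)
        cfg = SolverConfig(alpha=0.3, rho=0.9, **TIGHT)  # sparse solution
        fit = fit_elastic_net(XY(X, y), cfg)
        assert np.any(fit.coefficients == 0) and np.any(fit.coefficients != 0)
        assert kkt_violation(XY(X, y), fit, cfg) < 1e-8

    def test_nonconvergence_flagged_not_raised(self):
        rng = np.random.default_rng(5)
        X, y = rng.normal(size=(10, 8)), rng.normal(size=10)
        fit = fit_elastic_net(XY(X, y), SolverConfig(alpha=0.01, rho=0.5, max_sweeps=1, tol=1e-14))
        assert fit.converged is False

    def test_nonfinite_design_rejected(self):
        X = np.ones((3, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_elastic_net(XY(X, np.ones(3)))

    def test_standardize_switch_recovers_original_scale(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4)) * np.array([1.0, 10.0, 0.1, 5.0])
        y = X @ np.array([1.0, 0.2, -3.0, 0.0]) + rng.normal(size=30) * 0.1
        cfg = SolverConfig(alpha=0.0, standardize=True, **TIGHT)
        fit = fit_elastic_net(XY(X, y), cfg)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(30), X]), y, rcond=None
        )
        assert fit.intercept == pytest.approx(coef[0], abs=1e-6)
        np.testing.assert_allclose(fit.coefficients, coef[1:], atol=1e-6)

    def test_shuffled_sweep_order_reaches_same_optimum(self):
        rng = np.random.default_rng(7)
        X, y = rng.normal(size=(15, 6)), rng.normal(size=15)
        cfg_c = SolverConfig(alpha=0.1, rho=0.5, **TIGHT)
        cfg_s = SolverConfig(alpha=0.1, rho=0.5, shuffle=True, seed=99, **TIGHT)
        a = fit_elastic_net(XY(X, y), cfg_c)
        b = fit_elastic_net(XY(X, y), cfg_s)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_kkt_holds_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 15))
        p = int(rng.integers(1, 12))
        X, y = rng.normal(size=(m, p)), rng.normal(size=m)
        alpha = float(rng.uniform(0.0, 0.5))
        rho = float(rng.uniform(0.0, 1.0))
        cfg = SolverConfig(alpha=alpha, rho=rho, **TIGHT)
        fit = fit_elastic_net(XY(X, y), cfg)
        assert kkt_violation(XY(X, y), fit, cfg) < 1e-6


class TestLimits:
    def test_ridge_limit_matches_closed_form(self):
        rng = np.random.default_rng(8)
        X, y = rng.normal(size=(25, 6)), rng.normal(size=25)
        alpha = 0.2
        fit = fit_elastic_net(XY(X, y), SolverConfig(alpha=alpha, rho=0.0, **TIGHT))
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        m = len(y)
        beta = np.linalg.solve(Xc.T @ Xc / m + alpha * np.eye(6), Xc.T @ yc / m)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_lasso_limit_is_sparse_and_optimal(self):
        rng = np.random.default_rng(9)
        X, y = rng.normal(size=(20, 15)), rng.normal(size=20)
        cfg = SolverConfig(alpha=0.2, rho=1.0, **TIGHT)
        fit = fit_elastic_net(XY(X, y), cfg)
        assert np.sum(fit.coefficients != 0) < 15
        assert kkt_violation(XY(X, y), fit, cfg) < 1e-8

    def test_ols_limit_matches_lstsq(self):
        rng = np.random.default_rng(10)
        X, y = rng.normal(size=(30, 5)), rng.normal(size=30)
        fit = fit_elastic_net(XY(X, y), SolverConfig(alpha=0.0, **TIGHT))
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(30), X]), y, rcond=None)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-8)
        np.testing.assert_allclose(fit.coefficients, coef[1:], atol=1e-8)


class TestPredict:
    def test_intercept_only(self):
        d = XY(np.zeros((4, 3)), np.full(4, 2.5))
        fit = fit_elastic_net(d, SolverConfig(alpha=0.15, rho=0.01, **TIGHT))
        np.testing.assert_allclose(predict(fit, np.ones((2, 3))), 2.5, atol=1e-9)

    def test_neglog_inverse_maps_zero_to_unit_viability(self):
        d = XY(np.zeros((4, 2)), np.zeros(4))
        fit = fit_elastic_net(d, SolverConfig(**TIGHT))
        fit.transform_tag = "neglog"
        np.testing.assert_allclose(predict_viability(fit, np.zeros((3, 2))), 1.0)

    def test_interpolating_fit_reproduces_training_responses(self):
        rng = np.random.default_rng(11)
        X, y = rng.normal(size=(5, 6)), rng.normal(size=5)  # M <= p+1
        fit = fit_elastic_net(XY(X, y), SolverConfig(alpha=0.0, **TIGHT))
        np.testing.assert_allclose(predict(fit, X), y, atol=1e-6)

    def test_column_mismatch_rejected(self):
        fit = fit_elastic_net(XY(np.ones((3, 2)), np.arange(3.0)), SolverConfig())
        with pytest.raises(ValueError):
            predict(fit, np.ones((2, 5)))


class TestLoocv:
    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(12)
        d = XY(rng.uniform(size=(6, 3)), np.full(6, 0.8))
        cv = loocv(d, SolverConfig())
        np.testing.assert_allclose(cv.predictions, 0.8, atol=1e-6)

    def test_heldout_prediction_immune_to_own_response(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(size=(10, 4))
        y = X @ np.array([1.0, -0.5, 0.0, 0.3]) + rng.normal(size=10) * 0.05
        cfg = SolverConfig(alpha=0.1, rho=0.5, **TIGHT)
        base = loocv(XY(X, y), cfg)
        y2 = y.copy()
        y2[4] += 100.0  # poison one held-out response
        poisoned = loocv(XY(X, y2), cfg)
        assert poisoned.predictions[4] == pytest.approx(base.predictions[4], abs=1e-6)

    def test_prediction_invariant_to_order_of_other_rows(self):
        rng = np.random.default_rng(14)
        X, y = rng.uniform(size=(8, 3)), rng.uniform(size=8)
        cfg = SolverConfig(alpha=0.1, rho=0.3, **TIGHT)
        base = loocv(XY(X, y), cfg).predictions[0]
        perm = np.concatenate([[0], 1 + rng.permutation(7)])
        shuffled = loocv(XY(X[perm], y[perm]), cfg).predictions[0]
        assert shuffled == pytest.approx(base, abs=1e-8)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            loocv(XY(np.ones((2, 1)), np.arange(2.0)))
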