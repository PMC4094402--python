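"""Elastic-net regression by cyclic coordinate descent, with LOOCV.

The model is v_i = b0 + b1*A_{1,i} + ... + bp*A_{p,i} fit by minimizing

    F(b0, b) = (1/2M) * ||y - b0 - X b||_2^2
               + alpha*rho * ||b||_1
               + (alpha*(1-rho)/2) * ||b||_2^2

with the intercept b0 unpenalized. ``alpha`` sets the overall penalty
strength and ``rho`` the lasso fraction of the mix (rho=1 is the lasso,
rho=0 ridge, alpha=0 ordinary least squares). The default alpha=0.15,
rho=0.01 keeps many small coefficients (mostly-ridge) while still zeroing
clearly irrelevant kinases.

Each coordinate update is the exact one-dimensional minimizer

    b_j <- S(z_j, alpha*rho) / (c_j + alpha*(1-rho)),
    z_j = (1/M) x_j^T (r + x_j b_j),   c_j = (1/M) x_j^T x_j,

with S the soft-threshold operator and r the current residual; the
intercept is refreshed by the mean residual. Exact coordinate minimization
makes F non-increasing across sweeps, and the returned solution carries a
KKT certificate (see :func:`kkt_violation`).

Predictors are not standardized by default: residual activities already
share the [0, 1] scale and the objective above has no per-column scaling.
A ``standardize`` switch is provided for data on heterogeneous scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .treatments import DesignMatrix, Transform

logger = logging.getLogger(__name__)

__all__ = [
    "SolverConfig",
    "FitResult",
    "LoocvResult",
    "objective",
    "fit_elastic_net",
    "predict",
    "predict_viability",
    "kkt_violation",
    "loocv",
]


@dataclass(frozen=True)
class SolverConfig:
    """Elastic-net penalty and convergence settings.

    alpha : overall penalty magnitude (>= 0); 0 turns the fit into OLS.
    rho : lasso fraction in [0, 1]; 1 = pure lasso, 0 = pure ridge.
    tol : stop when the largest coefficient change in a sweep falls below.
    max_sweeps : hard cap on coordinate sweeps.
    seed : drives the sweep order when ``shuffle`` is on.
    shuffle : visit coordinates in a seeded random order instead of the
        column order (a fixed permutation per fit; default cyclic).
    standardize : scale columns to unit standard deviation before fitting
        and return coefficients on the original scale.
    """

    alpha: float = 0.15
    rho: float = 0.01
    tol: float = 1e-7
    max_sweeps: int = 10_000
    seed: int = 0
    shuffle: bool = False
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not 0 <= self.rho <= 1:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_sweeps < 1:
            raise ValueError(f"max_sweeps must be >= 1, got {self.max_sweeps}")


@dataclass
class FitResult:
    """Fitted intercept and coefficients with solver diagnostics."""

    intercept: float
    coefficients: np.ndarray
    kinase_ids: list[str]
    transform_tag: Transform
    objective_value: float
    n_sweeps: int
    converged: bool


@dataclass
class LoocvResult:
    """Leave-one-out predictions and both R-squared flavours.

    ``r_squared`` is the squared Pearson correlation between held-out
    predictions and observations (the primary report);
    ``r_squared_score`` is 1 - SS_res / SS_tot on the same pairs.
    """

    predictions: np.ndarray
    observed: np.ndarray
    r_squared: float
    r_squared_score: float
    n_folds_converged: int


def _as_xy(design) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(design, "X"):
        return np.asarray(design.X, float), np.asarray(design.y, float)
    raise TypeError("expected a DesignMatrix-like object with X and y")


def objective(design, beta0: float, beta, config: SolverConfig) -> float:
    """Evaluate the penalized objective F at (beta0, beta)."""
    X, y = _as_xy(design)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (X.shape[1],):
        raise ValueError(
            f"beta length {beta.shape} does not match {X.shape[1]} predictors"
        )
    r = y - beta0 - X @ beta
    m = X.shape[0]
    return float(
        0.5 / m * r @ r
        + config.alpha * config.rho * np.abs(beta).sum()
        + 0.5 * config.alpha * (1 - config.rho) * beta @ beta
    )


@njit(cache=True)
def _cd_solve(X, y, beta0, beta, lam1, lam2, tol, max_sweeps, order):
    """Cyclic coordinate descent on the elastic-net objective (in place)."""
    m, p = X.shape
    r = y - beta0 - X @ beta
    c = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(m):
            s += X[i, j] * X[i, j]
        c[j] = s / m
    n_sweeps = 0
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for t in range(p):
            j = order[t]
            denom = c[j] + lam2
            if denom == 0.0:
                new = 0.0
            else:
                z = 0.0
                for i in range(m):
                    z += X[i, j] * r[i]
                z = z / m + c[j] * beta[j]
                a = abs(z) - lam1
                if a <= 0.0:
                    new = 0.0
                else:
                    new = a / denom if z > 0 else -a / denom
            d = new - beta[j]
            if d != 0.0:
                for i in range(m):
                    r[i] -= X[i, j] * d
                beta[j] = new
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        mr = 0.0
        for i in range(m):
            mr += r[i]
        mr /= m
        if mr != 0.0:
            beta0 += mr
            for i in range(m):
                r[i] -= mr
            if abs(mr) > max_delta:
                max_delta = abs(mr)
        n_sweeps += 1
        if max_delta < tol:
            converged = True
            break
    return beta0, n_sweeps, converged


def fit_elastic_net(
    design,
    config: SolverConfig = SolverConfig(),
    warm_start: FitResult | None = None,
) -> FitResult:
    """Fit the elastic net on a design matrix by coordinate descent.

    Non-convergence within ``max_sweeps`` is reported on the result
    (``converged=False``), not raised. ``warm_start`` seeds the
    coefficients, e.g. with the full-data fit during cross-validation; the
    problem is convex, so the optimum does not depend on the start.
    """
    X, y = _as_xy(design)
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 treatments, got {X.shape[0]}")
    if X.shape[1] < 1:
        raise ValueError("need at least one predictor")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design contains non-finite values")

    scale = None
    if config.standardize:
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        X = X / scale

    p = X.shape[1]
    beta = np.zeros(p)
    beta0 = float(np.mean(y))
    if warm_start is not None:
        beta = np.array(warm_start.coefficients, dtype=float)
        if scale is not None:
            beta = beta * scale
        beta0 = float(warm_start.intercept)
    order = np.arange(p, dtype=np.int64)
    if config.shuffle:
        order = np.random.default_rng(config.seed).permutation(p)

    Xf = np.asfortranarray(X, dtype=np.float64)
    beta0, n_sweeps, converged = _cd_solve(
        Xf,
        np.ascontiguousarray(y, dtype=np.float64),
        beta0,
        beta,
        config.alpha * config.rho,
        config.alpha * (1 - config.rho),
        config.tol,
        config.max_sweeps,
        order,
    )
    if not converged:
        logger.warning(
            "coordinate descent did not converge in %d sweeps", config.max_sweeps
        )
    if scale is not None:
        beta = beta / scale
    kinase_ids = list(getattr(design, "kinase_ids", [f"k{j}" for j in range(p)]))
    return FitResult(
        intercept=float(beta0),
        coefficients=beta,
        kinase_ids=kinase_ids,
        transform_tag=getattr(design, "transform_tag", "linear"),
        objective_value=objective(design, beta0, beta, config),
        n_sweeps=n_sweeps,
        converged=converged,
    )


def predict(fit: FitResult, design_rows) -> np.ndarray:
    """Predicted response b0 + X b for new predictor rows.

    For a ``neglog`` fit the output is on the -log(viability) scale; use
    :func:`predict_viability` to map back to viability fractions.
    """
    X = design_rows.X if hasattr(design_rows, "X") else np.asarray(design_rows, float)
    if X.shape[1] != fit.coefficients.size:
        raise ValueError(
            f"{X.shape[1]} columns do not match {fit.coefficients.size} coefficients"
        )
    return fit.intercept + X @ fit.coefficients


def predict_viability(fit: FitResult, design_rows) -> np.ndarray:
    """Predicted viability fraction, inverting -log for neglog fits."""
    yhat = predict(fit, design_rows)
    if fit.transform_tag == "neglog":
        return np.exp(-yhat)
    return yhat


def kkt_violation(design, fit: FitResult, config: SolverConfig) -> float:
    """Largest violation of the optimality (KKT) conditions at ``fit``.

    At the optimum, (1/M) x_j^T r - alpha*(1-rho)*b_j equals
    alpha*rho*sign(b_j) for every active coordinate, its magnitude is
    bounded by alpha*rho for zero coordinates, and the residual has zero
    mean. Returns the largest absolute deviation across all conditions.
    """
    X, y = _as_xy(design)
    beta = fit.coefficients
    r = y - fit.intercept - X @ beta
    m = X.shape[0]
    g = X.T @ r / m - config.alpha * (1 - config.rho) * beta
    lam1 = config.alpha * config.rho
    active = beta != 0
    viol = abs(float(np.mean(r)))
    if np.any(active):
        viol = max(viol, float(np.max(np.abs(g[active] - lam1 * np.sign(beta[active])))))
    if np.any(~active):
        viol = max(viol, float(np.max(np.maximum(np.abs(g[~active]) - lam1, 0.0))))
    return viol


def loocv(design, config: SolverConfig = SolverConfig()) -> LoocvResult:
    """Leave-one-out cross-validation of the elastic-net model.

    Each treatment is predicted by a model trained on the other M-1
    treatments only (warm-started from the full-data fit). Reports the
    squared Pearson correlation between predictions and observations, and
    the 1 - SS_res/SS_tot score on the same pairs.
    """
    X, y = _as_xy(design)
    m = X.shape[0]
    if m < 3:
        raise ValueError(f"LOOCV needs at least 3 treatments, got {m}")
    full = fit_elastic_net(design, config)
    preds = np.empty(m)
    n_conv = 0

    @dataclass
    class _Sub:
        X: np.ndarray
        y: np.ndarray

    for i in range(m):
        mask = np.ones(m, dtype=bool)
        mask[i] = False
        sub = _Sub(X=X[mask], y=y[mask])
        if np.ptp(sub.y) == 0:
            logger.info("fold %d: constant training response; predicting its mean", i)
            preds[i] = sub.y[0]
            n_conv += 1
            continue
        fit = fit_elastic_net(sub, config, warm_start=full)
        n_conv += int(fit.converged)
        preds[i] = fit.intercept + X[i] @ fit.coefficients

    if np.ptp(preds) == 0 or np.ptp(y) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(preds, y)[0, 1] ** 2)
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    score = 1 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return LoocvResult(
        predictions=preds,
        observed=y.copy(),
        r_squared=r2,
        r_squared_score=float(score),
        n_folds_converged=n_conv,
    )
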