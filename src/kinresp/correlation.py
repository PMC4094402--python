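"""Per-kinase Pearson correlation screening with BH-FDR.

Ranks kinases by how strongly their residual activity across treatments
correlates with a response (selectivity or viability). This is the
single-predictor companion to the multivariate elastic-net model: a kinase
whose inhibition tracks the response shows a large |r| and a small p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["CorrelationRow", "pearson_with_p", "bh_fdr", "correlate_kinases"]


@dataclass
class CorrelationRow:
    kinase_id: str
    r: float
    p_value: float
    fdr: float


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided p-value.

    The p-value comes from the t statistic r * sqrt((M-2) / (1-r^2)) on
    M-2 degrees of freedom. Requires M >= 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length 1-d vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj(i) = min_{j >= i} p_(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def correlate_kinases(design, response=None) -> list[CorrelationRow]:
    """Correlate each kinase's activity column with a response vector.

    Parameters
    ----------
    design
        A :class:`~kinresp.treatments.DesignMatrix` (its own ``y`` is used
        when ``response`` is None), or any (n_treatments, n_kinases) array
        paired with an explicit ``response``.
    response
        Response vector aligned to treatment rows (selectivity or
        viability); overrides ``design.y`` when given.

    Returns
    -------
    list of CorrelationRow
        One row per non-constant kinase, sorted by p-value ascending (ties
        broken by |r| descending, then kinase symbol). FDR is BH-adjusted
        across the non-constant kinases only; constant-activity kinases are
        excluded from the family and logged.
    """
    if hasattr(design, "X"):
        X = np.asarray(design.X, dtype=float)
        kinase_ids = list(design.kinase_ids)
        y = design.y if response is None else np.asarray(response, dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        kinase_ids = [f"k{j}" for j in range(X.shape[1])]
        if response is None:
            raise ValueError("response required when design is a bare matrix")
        y = np.asarray(response, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError(
            f"response length {y.shape} does not match {X.shape[0]} treatments"
        )
    if X.shape[0] < 3:
        raise ValueError("need at least 3 treatments to correlate")

    tested: list[tuple[str, float, float]] = []
    for j, kinase in enumerate(kinase_ids):
        col = X[:, j]
        if np.ptp(col) == 0:
            logger.info("kinase %s has constant activity; excluded from FDR", kinase)
            continue
        r, p = pearson_with_p(col, y)
        tested.append((kinase, r, p))
    if not tested:
        return []
    fdr = bh_fdr([p for _, _, p in tested])
    rows = [
        CorrelationRow(kinase_id=k, r=r, p_value=p, fdr=q)
        for (k, r, p), q in zip(tested, fdr)
    ]
    rows.sort(key=lambda row: (row.p_value, -abs(row.r), row.kinase_id))
    return rows
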