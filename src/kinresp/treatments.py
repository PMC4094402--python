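"""Treatments, pair-activity combination, selectivity, and design matrices.

A treatment is a single kinase inhibitor or an unordered pair of two
inhibitors applied together. For a pair, the residual activity a kinase
retains is modelled as the product of the two drugs' residual activities
(independent action on each kinase). Regression designs are built either on
the raw activity scale (``linear``) or on the negative-log scale
(``neglog``), where the multiplicative viability model becomes linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal, Sequence

import numpy as np

if TYPE_CHECKING:
    from .io import ActivityMatrix, ScreenTable

Transform = Literal["linear", "neglog"]

#: Default clip floor applied to activities and viabilities before -log.
DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class Treatment:
    """A single drug or an unordered drug pair.

    Pairs are stored canonically with the two ids sorted, so
    ``Treatment(("B", "A")) == Treatment(("A", "B"))``.
    """

    drugs: tuple[str, ...]

    def __init__(self, drugs: Sequence[str]):
        drugs = tuple(str(d) for d in drugs)
        if len(drugs) not in (1, 2):
            raise ValueError(f"a treatment has 1 or 2 drugs, got {len(drugs)}")
        if len(drugs) == 2:
            if drugs[0] == drugs[1]:
                raise ValueError(f"pair repeats drug {drugs[0]!r}")
            drugs = tuple(sorted(drugs))
        object.__setattr__(self, "drugs", drugs)

    @property
    def is_pair(self) -> bool:
        return len(self.drugs) == 2

    def __str__(self) -> str:
        return "+".join(self.drugs)


@dataclass
class DesignMatrix:
    """Regression design: treatments x kinases predictors with a response.

    ``X[i, k]`` is the (possibly pair-combined, possibly -log-transformed)
    residual activity of kinase ``k`` under treatment ``i``; ``y[i]`` is the
    matching response (viability, or -log viability for ``neglog``).
    """

    treatments: list[Treatment]
    kinase_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    transform_tag: Transform = "linear"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.treatments), len(self.kinase_ids)):
            raise ValueError(
                f"X shape {self.X.shape} does not match "
                f"{len(self.treatments)} treatments x {len(self.kinase_ids)} kinases"
            )
        if self.y.shape != (len(self.treatments),):
            raise ValueError("y length does not match number of treatments")

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def n_kinases(self) -> int:
        return len(self.kinase_ids)


def pair_activity(a1: float, a2: float):
    """Residual activity of a kinase under a drug pair: the product a1 * a2.

    Both inputs must lie in [0, 1]; the product is symmetric and stays in
    [0, 1]. An unaffected kinase (activity 1) is the identity element.
    Accepts scalars or arrays (elementwise).
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    for name, a in (("a1", a1), ("a2", a2)):
        if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = a1 * a2
    return float(out) if out.ndim == 0 else out


def selectivity(v_n: float, v_c: float) -> float:
    """Selectivity S = v_N / v_C of a treatment.

    ``v_n`` is the viability (fraction of untreated control) of the normal
    cell line, ``v_c`` of the cancer line. S > 1 means the treatment spares
    normal cells relative to cancer cells.
    """
    if v_n < 0:
        raise ValueError(f"normal viability must be >= 0, got {v_n}")
    if v_c <= 0:
        raise ZeroDivisionError(
            f"cancer viability must be > 0 to form selectivity, got {v_c}; "
            "clip small viabilities upstream if needed"
        )
    return v_n / v_c


def treatment_activity_row(
    treatment: Treatment, profiles: "ActivityMatrix"
) -> np.ndarray:
    """Per-kinase residual activity of a treatment on the linear scale."""
    rows = []
    for drug in treatment.drugs:
        if drug not in profiles.drug_index:
            raise KeyError(f"drug {drug!r} has no activity profile")
        rows.append(profiles.values[profiles.drug_index[drug]])
    if len(rows) == 1:
        return rows[0].copy()
    return pair_activity(rows[0], rows[1])


def build_design_matrix(
    screen: "ScreenTable",
    profiles: "ActivityMatrix",
    cell_line: str,
    transform: Transform = "linear",
    epsilon_a: float = DEFAULT_EPSILON,
    epsilon_v: float = DEFAULT_EPSILON,
) -> DesignMatrix:
    """Assemble the regression design for one cell line.

    Parameters
    ----------
    screen
        Viability table; every constituent drug must be profiled (apply
        :func:`kinresp.io.intersect_library` first).
    profiles
        Drug x kinase residual-activity matrix.
    cell_line
        Which cell line's viabilities form the response.
    transform
        ``linear``: X = A, y = v. ``neglog``: X = -log(max(A, epsilon_a)),
        y = -log(max(v, epsilon_v)), which linearizes the multiplicative
        viability model v = exp(b0) * prod_k A_k^(b_k).
    epsilon_a, epsilon_v
        Clip floors guarding the logarithm against exact zeros.
    """
    if cell_line not in screen.cell_lines:
        raise KeyError(f"cell line {cell_line!r} not in screen {screen.cell_lines}")
    treatments = [rec.treatment for rec in screen.records]
    X = np.empty((len(treatments), profiles.n_kinases), dtype=float)
    y = np.empty(len(treatments), dtype=float)
    for i, rec in enumerate(screen.records):
        X[i] = treatment_activity_row(rec.treatment, profiles)
        y[i] = rec.viability[cell_line]
    if transform == "neglog":
        X = -np.log(np.maximum(X, epsilon_a))
        y = -np.log(np.maximum(y, epsilon_v))
    elif transform != "linear":
        raise ValueError(f"unknown transform {transform!r}")
    return DesignMatrix(
        treatments=treatments,
        kinase_ids=list(profiles.kinase_ids),
        X=X,
        y=y,
        transform_tag=transform,
    )
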