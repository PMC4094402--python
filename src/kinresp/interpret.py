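"""Differential coefficient ranking and kinase-background pathway enrichment.

Fitting the viability model separately in a cancer and a normal cell line
yields two coefficient vectors beta^C and beta^N. A kinase with a large
positive difference beta^C - beta^N contributes to loss of viability more
in the cancer line than in the normal line, flagging it as a candidate for
a selective therapeutic response. The selected kinases are then tested for
over-representation in pathway gene sets with a one-sided hypergeometric
(Fisher exact) test, using the assayed kinome — not the whole genome — as
the background universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from .correlation import bh_fdr
from .io import GeneSetCollection
from .solver import FitResult

__all__ = [
    "DifferentialRow",
    "EnrichmentRow",
    "differential_ranking",
    "select_significant",
    "hypergeom_pvalue",
    "enrich_pathways",
    "write_enrichment_tsv",
]


@dataclass
class DifferentialRow:
    kinase_id: str
    beta_cancer: float
    beta_normal: float
    difference: float


@dataclass
class EnrichmentRow:
    set_id: str
    set_name: str
    n_hits: int        # significant kinases in the pathway (N_S)
    n_pathway: int     # background kinases in the pathway (N_T)
    p_value: float
    fdr: float


def differential_ranking(
    fit_cancer: FitResult, fit_normal: FitResult
) -> list[DifferentialRow]:
    """Rank kinases by beta^C - beta^N, descending.

    Both fits must come from designs with identical kinase order and the
    same transform. Ties in the difference are broken by kinase symbol for
    deterministic output.
    """
    if fit_cancer.kinase_ids != fit_normal.kinase_ids:
        raise ValueError("fits do not share the same kinase set/order")
    if fit_cancer.transform_tag != fit_normal.transform_tag:
        raise ValueError(
            f"fits use different transforms: {fit_cancer.transform_tag!r} "
            f"vs {fit_normal.transform_tag!r}"
        )
    rows = [
        DifferentialRow(
            kinase_id=k,
            beta_cancer=float(bc),
            beta_normal=float(bn),
            difference=float(bc - bn),
        )
        for k, bc, bn in zip(
            fit_cancer.kinase_ids, fit_cancer.coefficients, fit_normal.coefficients
        )
    ]
    rows.sort(key=lambda r: (-r.difference, r.kinase_id))
    return rows


def select_significant(
    ranking: list[DifferentialRow],
    rule: Literal["top_k", "min_difference"],
    threshold: float,
    use_absolute: bool = False,
) -> set[str]:
    """Pick the kinase set driving the enrichment analysis.

    ``top_k`` takes the ``threshold`` largest differences in ranking order;
    ``min_difference`` takes every kinase with difference >= threshold.
    With ``use_absolute`` the magnitude |beta^C - beta^N| is ranked and
    thresholded instead of the signed difference, so kinases that matter
    selectively in either cell line qualify (published differential tables
    list magnitudes).
    """
    if not ranking:
        raise ValueError("ranking is empty")
    key = (lambda r: abs(r.difference)) if use_absolute else (lambda r: r.difference)
    if rule == "top_k":
        k = int(threshold)
        if k <= 0 or k > len(ranking):
            raise ValueError(f"top_k requires 0 < k <= {len(ranking)}, got {k}")
        ordered = sorted(ranking, key=lambda r: (-key(r), r.kinase_id))
        return {row.kinase_id for row in ordered[:k]}
    if rule == "min_difference":
        return {row.kinase_id for row in ranking if key(row) >= threshold}
    raise ValueError(f"unknown selection rule {rule!r}")


def hypergeom_pvalue(
    n_hits: int, n_pathway: int, n_selected: int, n_background: int
) -> float:
    """One-sided over-representation probability P(X >= n_hits).

    X is hypergeometric: draw ``n_selected`` kinases from a background of
    ``n_background`` containing ``n_pathway`` pathway members; the p-value
    is the exact upper tail at the observed overlap ``n_hits``.
    """
    if not 0 <= n_hits <= min(n_pathway, n_selected):
        raise ValueError(
            f"n_hits={n_hits} inconsistent with n_pathway={n_pathway}, "
            f"n_selected={n_selected}"
        )
    if max(n_pathway, n_selected) > n_background:
        raise ValueError(
            f"pathway ({n_pathway}) and selection ({n_selected}) must fit in "
            f"the background ({n_background})"
        )
    if n_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(n_hits - 1, n_background, n_pathway, n_selected))


def enrich_pathways(
    significant: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``significant`` within each set.

    Pathway membership is first restricted to the ``background`` universe
    (the assayed kinases), so N_T counts background kinases only; pathways
    with no background member are skipped. BH-FDR is computed over the
    tested pathways. Rows are sorted by p-value ascending (ties by set_id).
    """
    significant = {s.strip().upper() for s in significant}
    background = {b.strip().upper() for b in background}
    if not background:
        raise ValueError("background is empty")
    if not significant <= background:
        missing = sorted(significant - background)[:5]
        raise ValueError(f"significant kinases not in background: {missing} ...")
    n_bg = len(background)
    n_sel = len(significant)
    rows: list[EnrichmentRow] = []
    for gs in sets:
        members = set(gs.members) & background
        if not members:
            continue
        hits = members & significant
        rows.append(
            EnrichmentRow(
                set_id=gs.set_id,
                set_name=gs.set_name,
                n_hits=len(hits),
                n_pathway=len(members),
                p_value=hypergeom_pvalue(len(hits), len(members), n_sel, n_bg),
                fdr=np.nan,
            )
        )
    if rows:
        adjusted = bh_fdr([r.p_value for r in rows])
        for row, q in zip(rows, adjusted):
            row.fdr = float(q)
    rows.sort(key=lambda r: (r.p_value, r.set_id))
    return rows


def write_enrichment_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tset_name\tn_hits\tn_pathway\tp_value\tfdr\n")
        for r in rows:
            fh.write(
                f"{r.set_id}\t{r.set_name}\t{r.n_hits}\t{r.n_pathway}\t"
                f"{r.p_value:.6g}\t{r.fdr:.6g}\n"
            )
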