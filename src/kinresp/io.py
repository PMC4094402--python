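"""Data model and file I/O: activity matrices, screen tables, gene sets.

Formats
-------
Activity matrix CSV
    Header ``drug_id,<kinase1>,<kinase2>,...``; one row per drug; every cell
    a residual activity in [0, 1] (0 = fully inhibited, 1 = unaffected).
Screen CSV
    Header ``drug_a,drug_b,<cell_line_1>,...``; ``drug_b`` empty for a
    single-drug treatment; remaining cells are viabilities as fraction of
    untreated control (values above 1 are legal: stimulated growth).
Gene sets
    Standard GMT: one set per line, tab-separated ``id, name, member...``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .treatments import Treatment, selectivity

logger = logging.getLogger(__name__)

__all__ = [
    "ActivityMatrix",
    "ScreenRecord",
    "ScreenTable",
    "GeneSet",
    "GeneSetCollection",
    "read_activity_matrix",
    "write_activity_matrix",
    "read_screen_table",
    "write_screen_table",
    "read_gene_sets",
    "write_gene_sets",
    "intersect_library",
]


class FormatError(ValueError):
    """Structural problem in an input file (header, arity, duplicates)."""


class ValidationError(ValueError):
    """A value violates its domain (range, sign, finiteness)."""


@dataclass
class ActivityMatrix:
    """Drugs x kinases residual-activity matrix, every entry in [0, 1]."""

    drug_ids: list[str]
    kinase_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.kinase_ids = [str(k) for k in self.kinase_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise FormatError("duplicate drug ids in activity matrix")
        if len(set(self.kinase_ids)) != len(self.kinase_ids):
            raise FormatError("duplicate kinase ids in activity matrix")
        if self.values.shape != (len(self.drug_ids), len(self.kinase_ids)):
            raise ValidationError(
                f"activity matrix shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.kinase_ids)} kinases"
            )
        bad = ~np.isfinite(self.values) | (self.values < 0) | (self.values > 1)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"activity out of [0, 1] at drug {self.drug_ids[i]!r}, "
                f"kinase {self.kinase_ids[j]!r}: {self.values[i, j]}"
            )
        self.drug_index = {d: i for i, d in enumerate(self.drug_ids)}
        self.kinase_index = {k: j for j, k in enumerate(self.kinase_ids)}

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_kinases(self) -> int:
        return len(self.kinase_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drug_ids, columns=self.kinase_ids)


@dataclass
class ScreenRecord:
    """One treatment with its viability (fraction of control) per cell line."""

    treatment: Treatment
    viability: dict[str, float]


@dataclass
class ScreenTable:
    """Viability screen: unique treatments x a fixed set of cell lines."""

    records: list[ScreenRecord]
    cell_lines: list[str]

    def __post_init__(self) -> None:
        seen: set[Treatment] = set()
        labels = set(self.cell_lines)
        for rec in self.records:
            if rec.treatment in seen:
                raise FormatError(f"duplicate treatment {rec.treatment}")
            seen.add(rec.treatment)
            if set(rec.viability) != labels:
                raise ValidationError(
                    f"treatment {rec.treatment} has cell lines "
                    f"{sorted(rec.viability)}, expected {sorted(labels)}"
                )
            for cl, v in rec.viability.items():
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(
                        f"viability of {rec.treatment} in {cl} is {v}; "
                        "must be finite and >= 0"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def viability_vector(self, cell_line: str) -> np.ndarray:
        """Viabilities of all treatments in one cell line, in record order."""
        if cell_line not in self.cell_lines:
            raise KeyError(f"unknown cell line {cell_line!r}")
        return np.array([r.viability[cell_line] for r in self.records])

    def selectivity_vector(self, normal: str, cancer: str) -> np.ndarray:
        """Selectivity S = v_N / v_C per treatment, in record order."""
        return np.array(
            [selectivity(r.viability[normal], r.viability[cancer]) for r in self.records]
        )

    def drugs(self) -> set[str]:
        return {d for r in self.records for d in r.treatment.drugs}


@dataclass
class GeneSet:
    set_id: str
    set_name: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Reactome pathways) read from a GMT file."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate set ids in gene-set collection")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def _normalize_symbol(symbol: str) -> str:
    # gene symbols are matched case-insensitively as trimmed uppercase
    return symbol.strip().upper()


def read_activity_matrix(path: str | Path) -> ActivityMatrix:
    """Read a drug x kinase residual-activity CSV (see module docstring)."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a drug_id column plus >=1 kinase column")
    drug_col = df.columns[0]
    kinases = [str(c) for c in df.columns[1:]]
    drugs = df[drug_col].astype(str).tolist()
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric activity cell ({exc})") from exc
    return ActivityMatrix(drug_ids=drugs, kinase_ids=kinases, values=values)


def write_activity_matrix(matrix: ActivityMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "drug_id"
    df.to_csv(path)


def read_screen_table(path: str | Path) -> ScreenTable:
    """Read a viability screen CSV (see module docstring).

    An empty ``drug_b`` cell marks a single-drug treatment. Pairs are
    unordered: rows ``D1,D2`` and ``D2,D1`` collide as duplicates.
    """
    df = pd.read_csv(path, dtype={0: str, 1: str}, keep_default_na=False)
    cols = [str(c) for c in df.columns]
    if len(cols) < 3 or cols[0] != "drug_a" or cols[1] != "drug_b":
        raise FormatError(
            f"{path}: header must start with 'drug_a,drug_b' then cell lines, got {cols[:2]}"
        )
    cell_lines = cols[2:]
    records = []
    for _, row in df.iterrows():
        drug_a = str(row["drug_a"]).strip()
        drug_b = str(row["drug_b"]).strip()
        drugs = [drug_a] if drug_b == "" else [drug_a, drug_b]
        try:
            viab = {cl: float(row[cl]) for cl in cell_lines}
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-numeric viability for treatment {'+'.join(drugs)}"
            ) from exc
        records.append(ScreenRecord(Treatment(drugs), viab))
    return ScreenTable(records=records, cell_lines=cell_lines)


def write_screen_table(screen: ScreenTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_a", "drug_b", *screen.cell_lines])
        for rec in screen.records:
            drugs = list(rec.treatment.drugs) + [""] * (2 - len(rec.treatment.drugs))
            writer.writerow(
                drugs + [repr(rec.viability[cl]) for cl in screen.cell_lines]
            )


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; duplicate members within a line are dropped (warned)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs id, name and >=1 member, "
                    f"got {len(fields)} fields"
                )
            set_id, set_name = fields[0].strip(), fields[1].strip()
            members: list[str] = []
            seen: set[str] = set()
            for raw in fields[2:]:
                sym = _normalize_symbol(raw)
                if not sym:
                    continue
                if sym in seen:
                    logger.warning(
                        "%s:%d: duplicate member %s in set %s dropped",
                        path, lineno, sym, set_id,
                    )
                    continue
                seen.add(sym)
                members.append(sym)
            sets.append(GeneSet(set_id=set_id, set_name=set_name, members=members))
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets:
            fh.write("\t".join([s.set_id, s.set_name, *s.members]) + "\n")


def intersect_library(screen: ScreenTable, profiles: ActivityMatrix) -> ScreenTable:
    """Keep only screen records whose every drug has an activity profile.

    The screening library is typically larger than the profiled one, so
    treatments touching unprofiled drugs carry no usable predictors. The
    number of retained and dropped records is logged. Idempotent.
    """
    profiled = set(profiles.drug_ids)
    kept = [
        rec for rec in screen.records
        if all(d in profiled for d in rec.treatment.drugs)
    ]
    logger.info(
        "intersect_library: retained %d of %d treatments (%d dropped)",
        len(kept), len(screen.records), len(screen.records) - len(kept),
    )
    return ScreenTable(records=kept, cell_lines=list(screen.cell_lines))
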