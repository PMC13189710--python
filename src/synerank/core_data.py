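"""Domain types and delimited-text IO for combination dose-response data.

The atomic observation is a :class:`MeasurementRecord`: two drugs (or one,
for monotherapy) at specific concentrations applied to one cell line, with
the measured response on the percent-growth scale (100 = untreated growth,
0 = full growth inhibition, negative = cell killing). Records sharing a
(drug pair, cell line) form a :class:`ResponseList` — the unit over which
the listwise ranking loss is computed, corresponding to one dose-response
matrix.

Drug pairs are treated as unordered throughout: pair(A, B) and pair(B, A)
name the same combination, which matters for leakage-controlled splits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrugRecord",
    "MeasurementRecord",
    "ResponseList",
    "ExpressionMatrix",
    "Dataset",
    "Dialect",
    "ValidationError",
    "RowError",
    "read_measurements",
    "write_measurements",
    "read_drug_table",
    "write_drug_table",
    "read_expression",
    "write_expression",
    "group_into_lists",
    "select_variable_genes",
]

# Permissive syntactic check: the OpenSMILES character repertoire.
_SMILES_RE = re.compile(r"^[A-Za-z0-9@+\-\[\]\(\)=#$%/\\.:*~]+$")


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


@dataclass(frozen=True)
class RowError:
    """One rejected input row, with its 1-based line number and reason."""

    line: int
    message: str


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str

    def __post_init__(self):
        if not self.smiles or not _SMILES_RE.match(self.smiles):
            raise ValidationError(
                f"drug {self.drug_id!r}: SMILES {self.smiles!r} fails the syntactic check"
            )


@dataclass(frozen=True)
class MeasurementRecord:
    """One (drug1, drug2, dose1, dose2, cell, response) tuple.

    Monotherapy is encoded as ``drug2_id is None`` together with
    ``dose2 == 0``; the two always agree. Doses are molar concentrations.
    """

    drug1_id: str
    drug2_id: str | None
    dose1: float
    dose2: float
    cell_id: str
    response: float

    def __post_init__(self):
        if self.dose1 <= 0:
            raise ValidationError(f"dose1 must be positive, got {self.dose1}")
        mono = self.drug2_id is None
        if mono != (self.dose2 == 0):
            raise ValidationError(
                "monotherapy requires drug2_id null and dose2 == 0 together "
                f"(drug2_id={self.drug2_id!r}, dose2={self.dose2})"
            )
        if self.dose2 < 0:
            raise ValidationError(f"dose2 must be non-negative, got {self.dose2}")

    @property
    def is_monotherapy(self) -> bool:
        return self.drug2_id is None

    def pair_key(self) -> tuple[str, str | None]:
        """Unordered drug-pair key; monotherapy keys as (drug, None)."""
        if self.drug2_id is None:
            return (self.drug1_id, None)
        a, b = sorted((self.drug1_id, self.drug2_id))
        return (a, b)


@dataclass
class ResponseList:
    """All measurements of one (unordered drug pair, cell line).

    ``entries`` holds (dose1, dose2, response) in the canonical pair
    orientation (drug1_id <= drug2_id lexicographically for combinations);
    ``indices`` holds the position of each entry in the source measurement
    collection, in the same order.
    """

    drug1_id: str
    drug2_id: str | None
    cell_id: str
    entries: list[tuple[float, float, float]]
    indices: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def is_monotherapy(self) -> bool:
        return self.drug2_id is None

    @property
    def responses(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries])


@dataclass
class ExpressionMatrix:
    """Genes x cell lines expression values."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"expression shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains missing/non-finite values")

    def column(self, cell_id: str) -> np.ndarray:
        return self.values[:, self.cell_ids.index(cell_id)]


@dataclass
class Dataset:
    drugs: list[DrugRecord]
    measurements: list[MeasurementRecord]
    expression: ExpressionMatrix

    def __post_init__(self):
        drug_ids = {d.drug_id for d in self.drugs}
        if len(drug_ids) != len(self.drugs):
            raise ValidationError("duplicate drug_id in drug table")
        cells = set(self.expression.cell_ids)
        for i, m in enumerate(self.measurements):
            if m.drug1_id not in drug_ids or (
                m.drug2_id is not None and m.drug2_id not in drug_ids
            ):
                raise ValidationError(f"measurement {i}: unknown drug id")
            if m.cell_id not in cells:
                raise ValidationError(f"measurement {i}: unknown cell id {m.cell_id!r}")

    @property
    def smiles_by_id(self) -> dict[str, str]:
        return {d.drug_id: d.smiles for d in self.drugs}


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping so differently headed exports load unchanged."""

    drug1: str = "drug1"
    drug2: str = "drug2"
    dose1: str = "dose1"
    dose2: str = "dose2"
    cell: str = "cell"
    response: str = "response"
    sep: str = ","

    def required(self) -> list[str]:
        return [self.drug1, self.drug2, self.dose1, self.dose2, self.cell, self.response]


def read_measurements(
    path: str | Path,
    dialect: Dialect = Dialect(),
    *,
    strict: bool = False,
) -> tuple[list[MeasurementRecord], list[RowError]]:
    """Load measurement rows, normalising monotherapy representation.

    Empty / NA drug2 or zero dose2 are normalised to (drug2=None, dose2=0).
    Rows violating invariants are collected as :class:`RowError` (or raised
    immediately when ``strict``). Returns (records, errors).
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required() if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")

    records: list[MeasurementRecord] = []
    errors: list[RowError] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after the header
        r = dict(zip(df.columns, row))
        try:
            drug2 = r[dialect.drug2].strip() or None
            dose2_raw = r[dialect.dose2].strip()
            dose2 = float(dose2_raw) if dose2_raw else 0.0
            if dose2 == 0.0:
                drug2 = None
            if drug2 is None:
                dose2 = 0.0
            rec = MeasurementRecord(
                drug1_id=r[dialect.drug1].strip(),
                drug2_id=drug2,
                dose1=float(r[dialect.dose1]),
                dose2=dose2,
                cell_id=r[dialect.cell].strip(),
                response=float(r[dialect.response]),
            )
        except (ValidationError, ValueError) as exc:
            if strict:
                raise ValidationError(f"line {line}: {exc}") from exc
            errors.append(RowError(line=line, message=str(exc)))
            continue
        records.append(rec)
    return records, errors


def write_measurements(
    records: Iterable[MeasurementRecord],
    path: str | Path,
    dialect: Dialect = Dialect(),
) -> None:
    rows = [
        {
            dialect.drug1: m.drug1_id,
            dialect.drug2: m.drug2_id if m.drug2_id is not None else "",
            dialect.dose1: repr(m.dose1),
            dialect.dose2: repr(m.dose2),
            dialect.cell: m.cell_id,
            dialect.response: repr(m.response),
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=dialect.required()).to_csv(path, sep=dialect.sep, index=False)


def read_drug_table(path: str | Path, sep: str = ",") -> list[DrugRecord]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValidationError(f"drug table missing column {col!r}")
    return [DrugRecord(r.drug_id, r.smiles) for r in df.itertuples(index=False)]


def write_drug_table(drugs: Iterable[DrugRecord], path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(
        [{"drug_id": d.drug_id, "smiles": d.smiles} for d in drugs]
    ).to_csv(path, sep=sep, index=False)


def read_expression(path: str | Path, sep: str = ",") -> ExpressionMatrix:
    """Genes in rows (first column = gene id), cell lines in columns."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids).to_csv(path, sep=sep)


def group_into_lists(measurements: Sequence[MeasurementRecord]) -> list[ResponseList]:
    """Partition measurements into response lists keyed by (unordered pair, cell).

    Entries of swapped-orientation records are re-oriented to the canonical
    (sorted) drug order so that duplicate dose pairs are detected regardless
    of how the combination was written. Every input record lands in exactly
    one list; monotherapy records form their own (drug, None, cell) lists.
    """
    lists: dict[tuple, ResponseList] = {}
    for idx, m in enumerate(measurements):
        d1, d2 = m.pair_key()
        key = (d1, d2, m.cell_id)
        dose1, dose2 = m.dose1, m.dose2
        if d2 is not None and m.drug1_id != d1:  # record stored in swapped orientation
            dose1, dose2 = dose2, dose1
        rl = lists.get(key)
        if rl is None:
            rl = ResponseList(drug1_id=d1, drug2_id=d2, cell_id=m.cell_id, entries=[])
            lists[key] = rl
        if any(e[0] == dose1 and e[1] == dose2 for e in rl.entries):
            raise ValidationError(
                f"duplicate dose pair ({dose1}, {dose2}) for key ({d1}, {d2}, {m.cell_id})"
            )
        rl.entries.append((dose1, dose2, m.response))
        rl.indices.append(idx)
    return list(lists.values())


def select_variable_genes(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k genes with the largest expression variance across cell lines.

    Variance is the population variance (ddof=0). The output is ordered by
    descending variance; ties keep the input gene order (stable sort), so
    the operation is deterministic and idempotent.
    """
    n_genes = len(expr.gene_ids)
    if not 0 < k <= n_genes:
        raise ValueError(f"k={k} out of range for {n_genes} genes")
    var = expr.values.var(axis=1, ddof=0)
    order = np.argsort(-var, kind="stable")[:k]
    return ExpressionMatrix(
        gene_ids=[expr.gene_ids[i] for i in order],
        cell_ids=list(expr.cell_ids),
        values=expr.values[order],
    )
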