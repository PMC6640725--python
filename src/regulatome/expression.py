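"""Expression ingestion, signed fold-change conventions, housekeeping QC.

Fold changes use the reciprocal-signed convention common in microarray
meta-analyses: a treated/control ratio r >= 1 is written as +r, a ratio
r < 1 as -1/r, so the value never falls in the open interval (-1, 1) and
a ratio of exactly 1 encodes as +1.0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import GenePanel, normalize_symbol

__all__ = [
    "DifferentialTable",
    "ExpressionError",
    "QCReport",
    "compute_differential",
    "housekeeping_qc",
    "ratio_to_signed",
    "read_differential_tsv",
    "signed_fold_change",
    "signed_to_ratio",
    "write_differential_tsv",
]


class ExpressionError(ValueError):
    """Invalid expression input or fold-change table."""


def ratio_to_signed(ratio: float) -> float:
    """Encode a positive treated/control ratio as a signed fold change."""
    if not ratio > 0:
        raise ExpressionError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def signed_to_ratio(value: float) -> float:
    """Decode a signed fold change back to a treated/control ratio."""
    if abs(value) < 1.0:
        raise ExpressionError(f"signed fold change in (-1, 1): {value}")
    return value if value >= 1.0 else -1.0 / value


def signed_fold_change(treated_mean: float, control_mean: float) -> float:
    """Signed fold change of two positive group means.

    Antisymmetric: swapping the arguments flips the sign (except at
    equality, which encodes as +1.0).
    """
    if not (treated_mean > 0 and control_mean > 0):
        raise ExpressionError(
            f"group means must be positive, got {treated_mean}, {control_mean}"
        )
    return ratio_to_signed(treated_mean / control_mean)


@dataclass(frozen=True)
class FoldRecord:
    fold_change: float
    p_value: float | None = None


@dataclass
class DifferentialTable:
    """Per-gene signed fold changes for one dataset/condition.

    ``records`` maps normalized gene symbols to :class:`FoldRecord`.
    """

    dataset_id: str
    records: dict[str, FoldRecord]
    treatment: str = ""
    disease_class: str = ""
    organism: str = ""
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dataset_id:
            raise ExpressionError("dataset_id must be non-empty")

    def genes(self) -> frozenset[str]:
        return frozenset(self.records)

    def fold_change(self, gene: str) -> float | None:
        rec = self.records.get(normalize_symbol(gene))
        return None if rec is None else rec.fold_change

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.records),
                "fold_change": [r.fold_change for r in self.records.values()],
                "p_value": [r.p_value for r in self.records.values()],
            }
        )


def compute_differential(
    matrix: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    treated: str = "treated",
    control: str = "control",
    log2_input: bool = False,
    dataset_id: str = "synthetic",
    **meta: str,
) -> DifferentialTable:
    """Naive two-group signed fold changes from an expression matrix.

    ``matrix`` is genes x samples.  Group means are taken on the scale
    given: linear intensities by default, or per-sample log2 values with
    ``log2_input=True`` (the ratio is then ``2**(mean_t - mean_c)``).
    """
    labels = pd.Series(dict(group_labels))
    missing = set(matrix.columns) - set(labels.index)
    if missing:
        raise ExpressionError(f"samples without group label: {sorted(missing)}")
    t_cols = [c for c in matrix.columns if labels[c] == treated]
    c_cols = [c for c in matrix.columns if labels[c] == control]
    if not t_cols or not c_cols:
        raise ExpressionError(
            f"both groups need >=1 sample (treated={len(t_cols)}, control={len(c_cols)})"
        )
    if matrix.isna().any().any():
        raise ExpressionError("expression matrix contains missing values")
    mean_t = matrix[t_cols].mean(axis=1)
    mean_c = matrix[c_cols].mean(axis=1)
    if log2_input:
        ratios = np.exp2(mean_t - mean_c)
    else:
        if (mean_t <= 0).any() or (mean_c <= 0).any():
            raise ExpressionError("linear intensities must have positive group means")
        ratios = mean_t / mean_c
    records = {
        normalize_symbol(str(g)): FoldRecord(ratio_to_signed(float(r)))
        for g, r in ratios.items()
    }
    if len(records) != len(matrix):
        raise ExpressionError("duplicate gene symbols after normalization")
    return DifferentialTable(dataset_id=dataset_id, records=records, **meta)


@dataclass(frozen=True)
class QCReport:
    """Housekeeping-gene QC across a collection of differential tables."""

    hk_values: Mapping[tuple[str, str], float]  # (gene, dataset) -> signed fc
    min_value: float
    max_value: float
    threshold: float
    missing_cells: int

    @property
    def passed(self) -> bool:
        return all(abs(v) < self.threshold for v in self.hk_values.values())


def housekeeping_qc(
    tables: Sequence[DifferentialTable],
    panel: GenePanel,
    threshold: float = 1.5,
) -> QCReport:
    """Check that housekeeping fold changes stay inside (-threshold, threshold).

    A dataset with high technical quality should leave housekeeping genes
    essentially unchanged between conditions; the QC passes when every
    available housekeeping value has magnitude strictly below the
    threshold.  Missing cells (a housekeeping gene absent from a table's
    platform) are counted, never imputed and never failed.
    """
    if not tables:
        raise ExpressionError("housekeeping_qc needs at least one table")
    values: dict[tuple[str, str], float] = {}
    missing = 0
    for table in tables:
        for gene in panel.members:
            fc = table.fold_change(gene)
            if fc is None:
                missing += 1
            else:
                values[(gene, table.dataset_id)] = fc
    if not values:
        raise ExpressionError(
            f"no {panel.name} panel gene present in any of the {len(tables)} tables"
        )
    vals = list(values.values())
    return QCReport(
        hk_values=values,
        min_value=min(vals),
        max_value=max(vals),
        threshold=threshold,
        missing_cells=missing,
    )


_META_FIELDS = ("dataset_id", "treatment", "disease_class", "organism")


def read_differential_tsv(
    path: str | Path, convention: str | None = None
) -> DifferentialTable:
    """Read a differential TSV: ``#key<TAB>value`` header lines, then
    columns ``gene``, ``fold_change`` [, ``p_value``].

    ``convention`` selects how the fold_change column is interpreted:
    ``signed`` (reciprocal-negative, stored as-is), ``ratio`` (positive
    ratios, converted), or ``log2`` (log2 ratios, converted).  When not
    given, a ``#convention`` metadata line in the file applies, falling
    back to ``signed``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    data_rows: list[tuple[int, list[str]]] = []
    header: list[str] | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = line.split("\t")
                if header[:2] != ["gene", "fold_change"]:
                    raise ExpressionError(
                        f"{path}:{lineno}: expected columns gene, fold_change"
                    )
                continue
            data_rows.append((lineno, line.split("\t")))
    if convention is None:
        convention = meta.get("convention", "signed")
    if convention not in ("signed", "ratio", "log2"):
        raise ExpressionError(f"unknown fold-change convention {convention!r}")
    records: dict[str, FoldRecord] = {}
    duplicates: list[str] = []
    for lineno, fields in data_rows:
        row = dict(zip(header, fields))
        gene = normalize_symbol(row["gene"])
        try:
            raw_fc = float(row["fold_change"])
        except ValueError as exc:
            raise ExpressionError(
                f"{path}:{lineno}: unparseable fold change {row['fold_change']!r}"
            ) from exc
        if convention == "signed":
            if abs(raw_fc) < 1.0:
                raise ExpressionError(
                    f"{path}:{lineno}: signed fold change in (-1,1): {raw_fc}"
                )
            fc = raw_fc
        elif convention == "ratio":
            fc = ratio_to_signed(raw_fc)
        else:  # log2
            fc = ratio_to_signed(float(2.0**raw_fc))
        p = float(row["p_value"]) if row.get("p_value") not in (None, "") else None
        if p is not None and not 0.0 <= p <= 1.0:
            raise ExpressionError(f"{path}:{lineno}: p_value outside [0,1]: {p}")
        if gene in records:
            duplicates.append(gene)
        records[gene] = FoldRecord(fc, p)
    if duplicates:
        raise ExpressionError(
            f"{path}: duplicate genes after normalization: {sorted(set(duplicates))}"
        )
    meta.pop("convention", None)
    kwargs = {f: meta.pop(f, "") for f in _META_FIELDS[1:]}
    return DifferentialTable(
        dataset_id=meta.pop("dataset_id", path.stem),
        records=records,
        metadata=meta,
        **kwargs,
    )


def write_differential_tsv(table: DifferentialTable, path: str | Path) -> None:
    """Write a differential table in the canonical signed-convention dialect."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"#dataset_id\t{table.dataset_id}\n")
    for key in _META_FIELDS[1:]:
        value = getattr(table, key)
        if value:
            buf.write(f"#{key}\t{value}\n")
    for key, value in table.metadata.items():
        buf.write(f"#{key}\t{value}\n")
    buf.write("#convention\tsigned\n")
    has_p = any(r.p_value is not None for r in table.records.values())
    buf.write("gene\tfold_change" + ("\tp_value" if has_p else "") + "\n")
    for gene, rec in table.records.items():
        line = f"{gene}\t{rec.fold_change:g}"
        if has_p:
            line += "\t" + ("" if rec.p_value is None else f"{rec.p_value:g}")
        buf.write(line + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
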