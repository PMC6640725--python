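"""Loaders for the packaged condition fixtures.

These small TSVs transcribe the screening study's printed per-condition
fold-change calls (LIUS, mild hyperthermia, oscillatory shear stress,
transcription-factor perturbations), the housekeeping-gene QC values,
and the redox / chromatin-factor panel screens.  They are the canonical
desk-scale inputs for reproducing the published counts and overlaps.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

from .expression import DifferentialTable, ExpressionError, FoldRecord, read_differential_tsv
from .registry import normalize_symbol

__all__ = [
    "CONDITION_FIXTURES",
    "load_condition_table",
    "load_housekeeping_tables",
    "load_panel_screen_tables",
]

CONDITION_FIXTURES: tuple[str, ...] = (
    "lius_cancer",
    "lius_noncancer",
    "hyperthermia_cancer",
    "hyperthermia_noncancer",
    "oss_noncancer",
    "tp53_kd_noncancer",
    "tp53_ko_cancer",
    "srf_ko_noncancer",
)

_SCREENS = {"redox": "redox_screen.tsv", "chromatin_factors": "chromatin_factor_screen.tsv"}


def _fixture_path(name: str) -> Path:
    path = resources.files("regulatome").joinpath("data", "fixtures", name)
    return Path(str(path))


def load_condition_table(name: str) -> DifferentialTable:
    """Load one packaged condition fixture as a differential table."""
    if name not in CONDITION_FIXTURES:
        raise ExpressionError(
            f"unknown fixture {name!r}; available: {', '.join(CONDITION_FIXTURES)}"
        )
    return read_differential_tsv(_fixture_path(f"{name}.tsv"))


def _load_long_format(filename: str) -> dict[str, DifferentialTable]:
    """Parse a long-format (dataset_id, gene, fold_change) fixture."""
    tables: dict[str, dict[str, FoldRecord]] = {}
    with _fixture_path(filename).open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            gene = normalize_symbol(row["gene"])
            tables.setdefault(row["dataset_id"], {})[gene] = FoldRecord(
                float(row["fold_change"])
            )
    return {
        ds: DifferentialTable(dataset_id=ds, records=recs)
        for ds, recs in tables.items()
    }


def load_housekeeping_tables() -> list[DifferentialTable]:
    """Per-dataset housekeeping fold changes (one table per series)."""
    return list(_load_long_format("housekeeping.tsv").values())


def load_panel_screen_tables(screen: str) -> dict[str, DifferentialTable]:
    """Per-dataset tables for the ``redox`` or ``chromatin_factors`` screen.

    Only above-threshold values are printed in the source screens, so
    panel genes absent from a table are unchanged-below-threshold, not
    missing (pass ``absent_as_unchanged=True`` to the panel classifier).
    """
    if screen not in _SCREENS:
        raise ExpressionError(f"unknown screen {screen!r}; available: {sorted(_SCREENS)}")
    return _load_long_format(_SCREENS[screen])
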