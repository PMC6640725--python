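"""Curated cell-death regulatome and auxiliary gene panels.

The registry packages a curated mapping from 13 canonical cell-death
modalities (apoptosis, MPT-driven necrosis, necroptosis, ferroptosis,
pyroptosis, parthanatos, entotic cell death, NETotic cell death,
lysosome-dependent cell death, autophagy-dependent cell death,
immunogenic cell death, mitotic death, anoikis) to gene symbols.  The
packaged data hold 390 type memberships over 299 distinct symbols; the
membership excess (390 - 299 = 91) is reported as ``multi_type_genes``
because that is the counting convention the curation reconciles to,
while the literal number of genes appearing under two or more types is
exposed separately as ``genes_in_multiple_types``.

Symbols are normalized by upper-casing and whitespace stripping only.
Rodent-cased symbols (``Nlrp1b``, ``Naip5``, ``Serpina3g``) are
upper-cased but deliberately NOT mapped to human orthologs: the curation
pools species without ortholog resolution.  An auditable alias table
(shipped alongside the lists, empty by default) is the only mechanism
for renaming a symbol; there are no silent fixes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

__all__ = [
    "CELL_DEATH_TYPES",
    "GenePanel",
    "RegulatomeRegistry",
    "RegistryError",
    "load_panel",
    "load_regulatome",
    "memberships_of",
    "normalize_symbol",
]

#: The 13 canonical cell-death modality labels.  The set is closed.
CELL_DEATH_TYPES: tuple[str, ...] = (
    "apoptosis",
    "MPT-driven necrosis",
    "necroptosis",
    "ferroptosis",
    "pyroptosis",
    "parthanatos",
    "entotic cell death",
    "NETotic cell death",
    "LDCD",
    "ADCD",
    "ICD",
    "mitotic death",
    "anoikis",
)

PANEL_NAMES: tuple[str, ...] = ("housekeeping", "redox", "chromatin_factors")


class RegistryError(ValueError):
    """Malformed packaged data or invalid registry query."""


def normalize_symbol(raw: str, alias_table: Mapping[str, str] | None = None) -> str:
    """Normalize a gene symbol token: strip, upper-case, resolve aliases.

    Normalization is idempotent.  Symbols without an alias entry are kept
    verbatim (apart from case/whitespace); there is no silent renaming.

    Raises
    ------
    RegistryError
        If ``raw`` is empty after stripping.
    """
    token = raw.strip().upper()
    if not token:
        raise RegistryError(f"empty gene symbol token: {raw!r}")
    if alias_table:
        token = alias_table.get(token, token)
    return token


def _data_path(name: str):
    return resources.files("regulatome").joinpath("data", name)


def _read_tsv(name: str) -> list[dict[str, str]]:
    path = _data_path(name)
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if None in row or any(v is None for v in row.values()):
                raise RegistryError(f"{name}:{lineno}: malformed row {row!r}")
            rows.append(row)
    return rows


@dataclass(frozen=True)
class RegulatomeRegistry:
    """The packaged 13-type cell-death regulatome.

    ``memberships`` maps each cell-death type to its ordered,
    within-type-deduplicated tuple of normalized gene symbols.
    """

    memberships: Mapping[str, tuple[str, ...]]
    alias_table: Mapping[str, str] = field(default_factory=dict)
    alias_reasons: Mapping[str, str] = field(default_factory=dict)

    @property
    def per_type_count(self) -> dict[str, int]:
        return {t: len(g) for t, g in self.memberships.items()}

    @property
    def total_memberships(self) -> int:
        return sum(len(g) for g in self.memberships.values())

    @property
    def all_genes(self) -> frozenset[str]:
        return frozenset(g for genes in self.memberships.values() for g in genes)

    @property
    def unique_genes(self) -> int:
        return len(self.all_genes)

    @property
    def multi_type_genes(self) -> int:
        """Membership excess: total memberships minus unique genes.

        This is the source counting convention (it equals the number of
        multi-type genes only when no gene spans three or more types; the
        packaged data do contain such genes, see
        ``genes_in_multiple_types``).
        """
        return self.total_memberships - self.unique_genes

    @property
    def genes_in_multiple_types(self) -> int:
        """Literal count of genes appearing under >= 2 cell-death types."""
        return sum(1 for g in self.all_genes if len(self.memberships_of(g)) >= 2)

    def memberships_of(self, gene: str) -> frozenset[str]:
        """Cell-death types a gene belongs to (empty set if unknown)."""
        g = normalize_symbol(gene, self.alias_table)
        return frozenset(t for t, genes in self.memberships.items() if g in genes)

    def validate(self) -> None:
        if set(self.memberships) != set(CELL_DEATH_TYPES):
            raise RegistryError(
                f"registry types {sorted(self.memberships)} != canonical 13 labels"
            )
        for t, genes in self.memberships.items():
            if len(set(genes)) != len(genes):
                raise RegistryError(f"type {t!r} has duplicate symbols after dedup")
        # alias graph is a forest into canonicals: no alias raw token is
        # itself the target of another alias, and no target is an alias raw
        raws = set(self.alias_table)
        targets = set(self.alias_table.values())
        if raws & targets:
            raise RegistryError(
                f"alias table chains symbols: {sorted(raws & targets)}"
            )


@dataclass(frozen=True)
class GenePanel:
    """A named auxiliary gene panel, optionally partitioned into subgroups."""

    name: str
    members: tuple[str, ...]
    subgroups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subgroups:
            pooled = [g for genes in self.subgroups.values() for g in genes]
            if sorted(pooled) != sorted(self.members):
                raise RegistryError(
                    f"panel {self.name!r}: subgroups do not partition members"
                )


def _load_alias_table() -> tuple[dict[str, str], dict[str, str]]:
    table: dict[str, str] = {}
    reasons: dict[str, str] = {}
    for row in _read_tsv("aliases.tsv"):
        raw = row["raw"].strip().upper()
        canonical = row["canonical"].strip().upper()
        if not raw or not canonical:
            raise RegistryError(f"aliases.tsv: blank alias entry {row!r}")
        table[raw] = canonical
        reasons[raw] = row.get("reason", "")
    return table, reasons


@lru_cache(maxsize=1)
def load_regulatome() -> RegulatomeRegistry:
    """Load the packaged regulatome.  Deterministic; validated on load.

    The packaged TSV transcribes the curated lists verbatim (one row per
    printed membership, including any within-type duplicates); loading
    deduplicates within a type while preserving first-occurrence order.
    """
    alias_table, alias_reasons = _load_alias_table()
    memberships: dict[str, list[str]] = {t: [] for t in CELL_DEATH_TYPES}
    for lineno, row in enumerate(_read_tsv("regulatome.tsv"), start=2):
        cdt = row["cell_death_type"]
        if cdt not in memberships:
            raise RegistryError(
                f"regulatome.tsv:{lineno}: unknown cell death type {cdt!r}"
            )
        sym = normalize_symbol(row["gene_symbol_raw"], alias_table)
        if sym != row["gene_symbol_canonical"].strip().upper():
            raise RegistryError(
                f"regulatome.tsv:{lineno}: canonical column disagrees with "
                f"normalization for {row['gene_symbol_raw']!r}"
            )
        if sym not in memberships[cdt]:
            memberships[cdt].append(sym)
    registry = RegulatomeRegistry(
        memberships={t: tuple(g) for t, g in memberships.items()},
        alias_table=alias_table,
        alias_reasons=alias_reasons,
    )
    registry.validate()
    # every alias entry must be exercised by a packaged list
    unused = set(alias_table) - {
        row["gene_symbol_raw"].strip().upper()
        for row in _read_tsv("regulatome.tsv")
    }
    if unused:
        raise RegistryError(f"alias entries unused by packaged lists: {sorted(unused)}")
    return registry


def memberships_of(gene: str, registry: RegulatomeRegistry) -> frozenset[str]:
    """Functional alias for :meth:`RegulatomeRegistry.memberships_of`."""
    return registry.memberships_of(gene)


@lru_cache(maxsize=None)
def load_panel(name: str) -> GenePanel:
    """Load a packaged auxiliary panel: housekeeping, redox, chromatin_factors."""
    if name not in PANEL_NAMES:
        raise RegistryError(
            f"unknown panel {name!r}; available panels: {', '.join(PANEL_NAMES)}"
        )
    members: list[str] = []
    subgroups: dict[str, list[str]] = {}
    for row in _read_tsv("panels.tsv"):
        if row["panel"] != name:
            continue
        sym = normalize_symbol(row["gene_symbol"])
        members.append(sym)
        sub = row["subgroup"].strip()
        if sub:
            subgroups.setdefault(sub, []).append(sym)
    if not members:
        raise RegistryError(f"panel {name!r} empty in packaged data")
    return GenePanel(
        name=name,
        members=tuple(members),
        subgroups={s: tuple(g) for s, g in subgroups.items()},
    )
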