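"""The 1.5-fold regulation classifier and cross-condition overlap layer.

A gene is called *up* when its signed fold change strictly exceeds the
threshold, *down* when it is strictly below the negated threshold, and
*unchanged* otherwise.  The comparison is strict ("more than"), matching
the screening rule the packaged fixtures were produced under.  Genes of
the universe that a dataset's platform never measured are reported
separately as *not measured* rather than being called unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .expression import DifferentialTable, ExpressionError
from .registry import GenePanel, RegulatomeRegistry, normalize_symbol

__all__ = [
    "AnnotatedCallTable",
    "ConditionCallSet",
    "OverlapResult",
    "RegulationCall",
    "annotate",
    "classify",
    "compare",
    "knockout_crossref",
    "panel_screen",
]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class RegulationCall:
    gene: str
    call: str  # up | down | unchanged
    fold_change: float


@dataclass(frozen=True)
class ConditionCallSet:
    """Up/down/unchanged calls for one condition over a stated gene universe."""

    dataset_id: str
    treatment: str
    disease_class: str
    threshold: float
    calls: tuple[RegulationCall, ...]
    not_measured: tuple[str, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def _genes(self, call: str) -> frozenset[str]:
        return frozenset(c.gene for c in self.calls if c.call == call)

    @property
    def up(self) -> frozenset[str]:
        return self._genes("up")

    @property
    def down(self) -> frozenset[str]:
        return self._genes("down")

    @property
    def unchanged(self) -> frozenset[str]:
        return self._genes("unchanged")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.up), len(self.down), len(self.unchanged))

    def fold_change(self, gene: str) -> float | None:
        for c in self.calls:
            if c.gene == gene:
                return c.fold_change
        return None


def _call(fc: float, threshold: float) -> str:
    if fc > threshold:
        return "up"
    if fc < -threshold:
        return "down"
    return "unchanged"


def classify(
    table: DifferentialTable,
    universe: Iterable[str],
    threshold: float = 1.5,
) -> ConditionCallSet:
    """Classify every universe gene measured in ``table`` at ``threshold``.

    The threshold comparison is strict: a fold change of exactly the
    threshold magnitude is *unchanged*.
    """
    if threshold < 1.0:
        raise ExpressionError(f"threshold must be >= 1, got {threshold}")
    norm_universe = sorted({normalize_symbol(g) for g in universe})
    if not norm_universe:
        raise ExpressionError("empty gene universe")
    calls = []
    not_measured = []
    for gene in norm_universe:
        rec = table.records.get(gene)
        if rec is None:
            not_measured.append(gene)
        else:
            calls.append(RegulationCall(gene, _call(rec.fold_change, threshold), rec.fold_change))
    return ConditionCallSet(
        dataset_id=table.dataset_id,
        treatment=table.treatment,
        disease_class=table.disease_class,
        threshold=threshold,
        calls=tuple(calls),
        not_measured=tuple(not_measured),
        metadata=dict(table.metadata),
    )


@dataclass(frozen=True)
class AnnotatedCallTable:
    """Called genes grouped per cell-death type (a multi-type gene repeats)."""

    per_type_up: Mapping[str, tuple[tuple[str, float], ...]]
    per_type_down: Mapping[str, tuple[tuple[str, float], ...]]

    def types_of(self, gene: str) -> frozenset[str]:
        return frozenset(
            t
            for mapping in (self.per_type_up, self.per_type_down)
            for t, entries in mapping.items()
            if any(g == gene for g, _ in entries)
        )


def annotate(callset: ConditionCallSet, registry: RegulatomeRegistry) -> AnnotatedCallTable:
    """List every up/down gene under each of its cell-death types.

    A called gene with no registry membership is listed under
    ``"unassigned"`` so the union over types always equals the called set.
    """
    per_up: dict[str, list[tuple[str, float]]] = {}
    per_down: dict[str, list[tuple[str, float]]] = {}
    for call in callset.calls:
        if call.call == "unchanged":
            continue
        bucket = per_up if call.call == "up" else per_down
        types = registry.memberships_of(call.gene) or {UNASSIGNED}
        for t in sorted(types):
            bucket.setdefault(t, []).append((call.gene, call.fold_change))
    return AnnotatedCallTable(
        per_type_up={t: tuple(v) for t, v in per_up.items()},
        per_type_down={t: tuple(v) for t, v in per_down.items()},
    )


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 1.0


@dataclass(frozen=True)
class OverlapResult:
    """Shared and discordant differential calls between two conditions."""

    shared_up: frozenset[str]
    shared_down: frozenset[str]
    discordant: frozenset[str]
    jaccard_up: float
    jaccard_down: float

    def __post_init__(self) -> None:
        assert not (self.shared_up | self.shared_down) & self.discordant


def compare(a: ConditionCallSet, b: ConditionCallSet) -> OverlapResult:
    """Overlap of up/down calls between two conditions (set semantics)."""
    return OverlapResult(
        shared_up=a.up & b.up,
        shared_down=a.down & b.down,
        discordant=(a.up & b.down) | (a.down & b.up),
        jaccard_up=_jaccard(a.up, b.up),
        jaccard_down=_jaccard(a.down, b.down),
    )


@dataclass(frozen=True)
class KnockoutCrossref:
    """Genes moving opposite in a transcription-factor perturbation dataset.

    ``down_in_a_up_in_ko`` collects genes called down in the reference
    condition and up after knocking out/down the factor — the pattern
    expected when the factor represses those genes downstream of the
    stimulus — and vice versa.
    """

    factor: str
    down_in_a_up_in_ko: frozenset[str]
    up_in_a_down_in_ko: frozenset[str]

    @property
    def opposite(self) -> frozenset[str]:
        return self.down_in_a_up_in_ko | self.up_in_a_down_in_ko


def knockout_crossref(
    reference: ConditionCallSet, ko_calls: ConditionCallSet
) -> KnockoutCrossref:
    factor = ko_calls.metadata.get("perturbed_factor", "")
    return KnockoutCrossref(
        factor=factor,
        down_in_a_up_in_ko=reference.down & ko_calls.up,
        up_in_a_down_in_ko=reference.up & ko_calls.down,
    )


def panel_screen(
    table: DifferentialTable,
    panel: GenePanel,
    threshold: float = 1.5,
    absent_as_unchanged: bool = True,
) -> dict[str, ConditionCallSet]:
    """Apply the classifier within each panel subgroup.

    Screen tables conventionally omit sub-threshold values, so a panel
    gene absent from the table is treated as unchanged-below-threshold by
    default (``absent_as_unchanged``); pass False to report it as not
    measured instead.
    """
    out: dict[str, ConditionCallSet] = {}
    subgroups = panel.subgroups or {panel.name: panel.members}
    for sub, genes in subgroups.items():
        cs = classify(table, genes, threshold)
        if absent_as_unchanged and cs.not_measured:
            calls = cs.calls + tuple(
                RegulationCall(g, "unchanged", 1.0) for g in cs.not_measured
            )
            cs = ConditionCallSet(
                dataset_id=cs.dataset_id,
                treatment=cs.treatment,
                disease_class=cs.disease_class,
                threshold=cs.threshold,
                calls=tuple(sorted(calls, key=lambda c: c.gene)),
                not_measured=(),
                metadata=cs.metadata,
            )
        out[sub] = cs
    return out
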