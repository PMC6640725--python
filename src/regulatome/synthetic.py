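"""Synthetic expression matrices and interaction tables with known truth.

The expression generator emulates two-condition, replicated,
intensity-scale microarray data: control samples fluctuate around a
common baseline with multiplicative log-normal noise (specified as a
standard deviation on the log2 scale), and treated samples additionally
carry planted multiplicative effects.  In the noiseless limit the
recovered fold change of a planted gene is exactly its effect.

The interaction generator lays genes out on synthetic chromosomes (one
chromosome per 50 genes, TSS spaced 2x10^8 bp apart so that interaction
magnitudes up to 10^8 bp can never be attributed to the wrong gene) and
places each partner site downstream of the gene's TSS with probability
``downstream_prob``, at a log-uniform magnitude.  Trans rows pointing at
a dedicated decoy chromosome are injected with probability
``trans_prob``.  All generators are pure functions of their spec,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import classify
from .clri import GenomicInterval, InteractionRecord, Promoter
from .expression import compute_differential
from .registry import load_regulatome

__all__ = [
    "RecoveryReport",
    "SyntheticExpressionSpec",
    "SyntheticInteractionSpec",
    "SyntheticError",
    "gen_expression",
    "gen_interactions",
    "recovery_experiment",
]

_TSS_SPACING = 200_000_000  # bp between synthetic TSSs; > 2 * max magnitude
_GENES_PER_CHROM = 50


class SyntheticError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Two-group replicated expression with planted multiplicative effects.

    ``planted_up``/``planted_down`` map gene names to effects >= 1 (a
    down effect e means the treated mean is baseline / e).  ``noise_sd``
    is the standard deviation of the per-measurement log2-scale noise.
    ``regulatome_fraction`` of the genes take symbols from the packaged
    regulatome (deterministically by seed); the rest get synthetic names.
    """

    n_genes: int = 200
    planted_up: Mapping[str, float] = field(default_factory=dict)
    planted_down: Mapping[str, float] = field(default_factory=dict)
    replicates: int = 3
    noise_sd: float = 0.1
    baseline: float = 100.0
    regulatome_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.replicates < 1:
            raise SyntheticError("n_genes and replicates must be >= 1")
        if self.noise_sd < 0 or self.baseline <= 0:
            raise SyntheticError("noise_sd must be >= 0 and baseline > 0")
        if not 0.0 <= self.regulatome_fraction <= 1.0:
            raise SyntheticError("regulatome_fraction must be in [0, 1]")
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise SyntheticError(f"genes planted both up and down: {sorted(overlap)}")
        for effect in (*self.planted_up.values(), *self.planted_down.values()):
            if effect < 1.0:
                raise SyntheticError(f"planted effects must be >= 1, got {effect}")


def _gene_names(spec: SyntheticExpressionSpec, rng: np.random.Generator) -> list[str]:
    names = [f"SYNG{i:04d}" for i in range(spec.n_genes)]
    n_reg = int(round(spec.regulatome_fraction * spec.n_genes))
    if n_reg:
        pool = sorted(load_regulatome().all_genes)
        chosen = rng.choice(len(pool), size=min(n_reg, len(pool)), replace=False)
        for i, j in enumerate(sorted(chosen)):
            names[i] = pool[j]
    for g in (*spec.planted_up, *spec.planted_down):
        if g not in names:
            raise SyntheticError(f"planted gene {g} not among generated gene names")
    return names


def gen_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Generate (matrix, group labels, truth table) from a spec.

    The matrix is genes x samples on the linear intensity scale; the
    truth table lists each gene's planted direction and effect.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec, rng)
    n_samples = 2 * spec.replicates
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_samples))
    matrix = spec.baseline * np.exp2(noise)
    effects = np.ones(spec.n_genes)
    direction = ["unchanged"] * spec.n_genes
    index = {g: i for i, g in enumerate(genes)}
    for g, e in spec.planted_up.items():
        effects[index[g]] = e
        direction[index[g]] = "up"
    for g, e in spec.planted_down.items():
        effects[index[g]] = 1.0 / e
        direction[index[g]] = "down"
    matrix[:, spec.replicates :] *= effects[:, None]
    samples = [f"control_{i}" for i in range(spec.replicates)] + [
        f"treated_{i}" for i in range(spec.replicates)
    ]
    labels = {s: ("control" if s.startswith("control") else "treated") for s in samples}
    truth = pd.DataFrame(
        {"gene": genes, "direction": direction, "effect": np.where(effects < 1, 1 / effects, effects)}
    )
    return pd.DataFrame(matrix, index=genes, columns=samples), labels, truth


@dataclass(frozen=True)
class SyntheticInteractionSpec:
    """Interaction tables with a controllable downstream-placement bias.

    Each of ``interactions_per_gene`` partner sites per gene is placed
    downstream of the TSS with probability ``downstream_prob`` at a
    magnitude drawn log-uniformly from ``magnitude_range`` (bp).
    """

    genes: tuple[str, ...]
    interactions_per_gene: int = 10
    downstream_prob: float = 0.5
    magnitude_range: tuple[float, float] = (1e4, 1e8)
    trans_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.genes:
            raise SyntheticError("need at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise SyntheticError("duplicate genes in interaction spec")
        if self.interactions_per_gene < 1:
            raise SyntheticError("interactions_per_gene must be >= 1")
        for p in (self.downstream_prob, self.trans_prob):
            if not 0.0 <= p <= 1.0:
                raise SyntheticError(f"probability outside [0,1]: {p}")
        lo, hi = self.magnitude_range
        if not 0 < lo < hi:
            raise SyntheticError(f"magnitude bounds must be positive, ordered: {lo}, {hi}")


def _synthetic_promoters(genes: tuple[str, ...]) -> dict[str, Promoter]:
    promoters: dict[str, Promoter] = {}
    for i, gene in enumerate(genes):
        chrom = f"synchr{i // _GENES_PER_CHROM + 1}"
        tss = _TSS_SPACING // 2 + (i % _GENES_PER_CHROM) * _TSS_SPACING
        if gene in promoters:
            raise SyntheticError(f"TSS collision for gene {gene}")
        promoters[gene] = Promoter(chrom=chrom, tss=tss, strand="+")
    return promoters


def gen_interactions(
    spec: SyntheticInteractionSpec,
) -> tuple[list[InteractionRecord], dict[str, Promoter]]:
    """Generate (interaction records, promoter table) from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    promoters = _synthetic_promoters(spec.genes)
    lo, hi = spec.magnitude_range
    records: list[InteractionRecord] = []
    for gene in spec.genes:
        prom = promoters[gene]
        for _ in range(spec.interactions_per_gene):
            if rng.random() < spec.trans_prob:
                partner = GenomicInterval("synchr_trans", 1_000_000, 1_001_000)
            else:
                magnitude = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                sign = 1 if rng.random() < spec.downstream_prob else -1
                pos = prom.tss + sign * magnitude
                # center the partner interval on the drawn point so the
                # midpoint anchor recovers the magnitude exactly
                partner = GenomicInterval(prom.chrom, pos - 500, pos + 500)
            anchor = GenomicInterval(prom.chrom, prom.tss, prom.tss + 1000)
            records.append(
                InteractionRecord(
                    anchor_a=anchor,
                    anchor_b=partner,
                    genes_a=(gene,),
                    genes_b=(),
                    method="synthetic",
                    cell_type="synthetic",
                )
            )
    return records, promoters


def write_interaction_tsv(records: list[InteractionRecord], path) -> None:
    """Emit records in the 1-based-inclusive tabulated interaction dialect."""
    lines = []
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.anchor_a.chrom,
                    str(r.anchor_a.start + 1),
                    str(r.anchor_a.end),
                    r.anchor_b.chrom,
                    str(r.anchor_b.start + 1),
                    str(r.anchor_b.end),
                    ",".join(r.genes_a),
                    ",".join(r.genes_b),
                    r.method,
                    r.cell_type,
                ]
            )
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_promoter_bed(promoters: Mapping[str, Promoter], path) -> None:
    lines = [
        f"{p.chrom}\t{p.tss}\t{p.tss + 1}\t{gene}\t0\t{p.strand if p.strand in '+-' else '+'}"
        for gene, p in promoters.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RecoveryReport:
    """Classifier performance against planted truth."""

    sensitivity: float
    specificity: float
    n_planted: int
    n_null: int
    false_calls: tuple[str, ...]
    missed: tuple[str, ...]


def recovery_experiment(
    spec: SyntheticExpressionSpec, threshold: float = 1.5
) -> RecoveryReport:
    """Generate data per ``spec``, classify, and score against the truth.

    Sensitivity counts planted genes recovered with the correct
    direction; specificity counts null genes left unchanged.
    """
    matrix, labels, truth = gen_expression(spec)
    table = compute_differential(matrix, labels, dataset_id=f"synthetic-{spec.seed}")
    callset = classify(table, matrix.index, threshold=threshold)
    truth_dir = dict(zip(truth["gene"], truth["direction"]))
    planted = [g for g, d in truth_dir.items() if d != "unchanged"]
    null = [g for g, d in truth_dir.items() if d == "unchanged"]
    called = {c.gene: c.call for c in callset.calls}
    hit = [g for g in planted if called.get(g) == truth_dir[g]]
    correct_null = [g for g in null if called.get(g) == "unchanged"]
    return RecoveryReport(
        sensitivity=len(hit) / len(planted) if planted else 1.0,
        specificity=len(correct_null) / len(null) if null else 1.0,
        n_planted=len(planted),
        n_null=len(null),
        false_calls=tuple(sorted(g for g in null if called.get(g) != "unchanged")),
        missed=tuple(sorted(set(planted) - set(hit))),
    )
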