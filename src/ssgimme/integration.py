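"""From enrichment scores and expression to reaction-level expression.

Three steps connect ssGSEA output to the GIMME input: (1) gene-set
weighting multiplies each gene's expression by a weight derived from the
NES of the significant sets containing it; (2) GPR evaluation collapses
gene values onto reactions (AND -> min, the complex is limited by its
scarcest subunit; OR -> max, the best isozyme carries the reaction);
(3) reactions whose rule is empty or entirely unmeasured get the NO_DATA
sentinel, which later protects them from removal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ssgimme.enrichment import EnrichmentResult, GeneSetCollection
from ssgimme.model_io import AND, EMPTY, GENE, OR, GPRTree, MetabolicModel

logger = logging.getLogger(__name__)

#: In-band marker for "no expression evidence"; serialized as "NA" in TSV
#: and mapped to the GIMME sentinel (-1) only at that interface.
NO_DATA = None

MULTIPLY_NES = "multiply_nes"
MULTIPLY_POSITIVE_NES = "multiply_positive_nes"


@dataclass
class WeightedExpression:
    """Gene expression after gene-set weighting, same units as the input.

    Genes in no (significant) set keep weight 1; provenance records, per
    reweighted gene, the contributing sets and the applied weight.
    """

    values: dict[str, float]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, gene: str) -> float:
        return self.values[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.values

    @classmethod
    def identity(cls, profile: pd.Series | Mapping[str, float]) -> "WeightedExpression":
        """All weights 1: the plain-GIMME degenerate case."""
        series = pd.Series(profile, dtype=float)
        return cls(values={g: float(v) for g, v in series.items()})


@dataclass
class ReactionExpression:
    """Reaction-level expression: every model reaction maps to a value or
    to NO_DATA; this is what GIMME thresholds and penalizes."""

    values: dict[str, float | None]

    def data_items(self) -> dict[str, float]:
        return {rid: v for rid, v in self.values.items() if v is not NO_DATA}

    def coverage(self) -> float:
        """Fraction of reactions with expression evidence."""
        if not self.values:
            return 0.0
        return len(self.data_items()) / len(self.values)

    def to_tsv(self) -> str:
        lines = ["reaction_id\texpression"]
        for rid, value in self.values.items():
            lines.append(f"{rid}\tNA" if value is NO_DATA else f"{rid}\t{value:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, path: str, sentinel: float | None = None) -> "ReactionExpression":
        frame = pd.read_csv(path, sep="\t", dtype={"reaction_id": str})
        values: dict[str, float | None] = {}
        for rid, raw in zip(frame["reaction_id"], frame["expression"]):
            if pd.isna(raw) or (sentinel is not None and float(raw) == sentinel):
                values[rid] = NO_DATA
            else:
                values[rid] = float(raw)
        return cls(values=values)


def gene_set_weighting(
    profile: pd.Series,
    scores: EnrichmentResult,
    sets: GeneSetCollection,
    mode: str = MULTIPLY_POSITIVE_NES,
    combine: str = "max",
    sample: str | None = None,
    significant_only: bool = True,
) -> WeightedExpression:
    """Weight a sample's gene expression by its gene-set enrichment.

    For every gene in at least one selected set, the per-set weight is the
    mode-transformed NES (``multiply_positive_nes``: max(NES, 0);
    ``multiply_nes``: |NES|), combined across the gene's sets by ``combine``
    (max or mean) and rescaled so the median weight over affected genes is
    1 — enrichment boosts or shrinks genes relative to each other without
    moving the overall expression scale the downstream threshold operates
    on. Genes in no selected set stay unchanged. By default only sets with
    |NES| >= z_cutoff (the ``significant`` flag) contribute.
    """
    sample = sample if sample is not None else profile.name
    if sample is None:
        raise ValueError("sample id required (unnamed profile)")
    rows = scores.for_sample(sample)
    if rows.empty and not scores.table.empty:
        raise ValueError(f"no enrichment scores for sample {sample!r}")
    if significant_only:
        rows = rows[rows["significant"]]
    if mode not in (MULTIPLY_NES, MULTIPLY_POSITIVE_NES):
        raise ValueError(f"unknown weighting mode {mode!r}")
    if combine not in ("max", "mean"):
        raise ValueError(f"unknown combine rule {combine!r}")

    per_gene: dict[str, list[tuple[str, float]]] = {}
    for set_name, nes in zip(rows["set"], rows["nes"]):
        raw = max(float(nes), 0.0) if mode == MULTIPLY_POSITIVE_NES else abs(float(nes))
        for gene in sets.genes(set_name):
            if gene in profile.index:
                per_gene.setdefault(gene, []).append((set_name, raw))

    combined = {
        gene: (max if combine == "max" else np.mean)([w for _, w in hits])
        for gene, hits in per_gene.items()
    }
    weights = {g: 1.0 for g in profile.index}
    provenance: dict[str, dict] = {}
    if combined:
        scale = float(np.median(list(combined.values())))
        if scale <= 1e-12:
            logger.warning(
                "median gene-set weight ~0 for sample %s; weighting disabled", sample
            )
        else:
            for gene, raw in combined.items():
                weights[gene] = float(raw) / scale
                provenance[gene] = {
                    "sets": [name for name, _ in per_gene[gene]],
                    "weight": weights[gene],
                }
    values = {g: float(profile[g]) * weights[g] for g in profile.index}
    return WeightedExpression(values=values, provenance=provenance)


IGNORE = "ignore"
PROPAGATE = "propagate"


def evaluate_gpr(
    gpr: GPRTree,
    expr: WeightedExpression | Mapping[str, float],
    missing_policy: str = IGNORE,
) -> float | None:
    """Collapse a GPR rule to one expression value (or NO_DATA).

    GENE -> the gene's value; AND -> min over children; OR -> max over
    children; EMPTY -> NO_DATA. Unmeasured genes: under ``ignore`` they are
    dropped from the aggregate (a node with no measured child is NO_DATA);
    under ``propagate`` any unmeasured child makes the node NO_DATA.
    """
    if missing_policy not in (IGNORE, PROPAGATE):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if gpr.kind == EMPTY:
        return NO_DATA
    if gpr.kind == GENE:
        try:
            return float(expr[gpr.gene])  # type: ignore[index]
        except KeyError:
            return NO_DATA
    child_values = [evaluate_gpr(child, expr, missing_policy) for child in gpr.children]
    if missing_policy == PROPAGATE and any(v is NO_DATA for v in child_values):
        return NO_DATA
    measured = [v for v in child_values if v is not NO_DATA]
    if not measured:
        return NO_DATA
    return min(measured) if gpr.kind == AND else max(measured)


def reaction_expression(
    model: MetabolicModel,
    expr: WeightedExpression | Mapping[str, float],
    missing_policy: str = IGNORE,
) -> ReactionExpression:
    """Evaluate every reaction's GPR against (weighted) gene expression."""
    values = {
        reaction.id: evaluate_gpr(reaction.gpr, expr, missing_policy)
        for reaction in model.reactions
    }
    result = ReactionExpression(values=values)
    logger.info(
        "reaction expression coverage: %.1f%% (%d/%d reactions with data)",
        100 * result.coverage(), len(result.data_items()), len(values),
    )
    return result


def provenance_json(weighted: WeightedExpression) -> str:
    return json.dumps(weighted.provenance, indent=1, sort_keys=True)
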