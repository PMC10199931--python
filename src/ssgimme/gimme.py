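"""GIMME: context-specific model extraction by penalized flux minimization.

Given reaction-level expression, reactions expressed below a threshold t
(a quantile of the data-bearing reaction values, default the 25th
percentile) receive a penalty c_i = t − x_i. The LP then minimizes the
penalty-weighted total flux Σ c_i·|v_i| subject to mass balance, bounds,
and the requirement that the objective (biomass) stays at or above a
fraction f (default 0.9) of the parent model's FBA optimum Z*. Reactions
that are penalized yet carry no flux in the penalty minimum are removed;
unmeasured reactions are protected from removal — the classical "weight
of −1" marker, realized here as an out-of-band sentinel carrying zero
penalty plus removal protection (a literal negative objective coefficient
would reward flux and unbound the LP). The optimal penalty sum is the
inconsistency score: how much low-expression flux the stated objective
still requires.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from ssgimme.enrichment import GeneSetCollection, SsgseaConfig, ssgsea
from ssgimme.fba_core import (
    FLUX_EPSILON,
    FluxDistribution,
    LPError,
    OPTIMAL,
    _LINPROG_STATUS,
    _LPProblem,
    fba,
    fva,
)
from ssgimme.integration import (
    IGNORE,
    MULTIPLY_POSITIVE_NES,
    NO_DATA,
    ReactionExpression,
    WeightedExpression,
    gene_set_weighting,
    reaction_expression,
)
from ssgimme.model_io import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GimmeConfig:
    """GIMME parameters. The defaults are the method's standard operating
    point: 25%-quantile threshold, objective tolerance 0.9, sentinel −1
    for unmeasured reactions, activity floor 10⁻⁶."""

    threshold_quantile: float = 0.25
    objective_fraction: float = 0.9
    no_data_sentinel: float = -1.0
    flux_epsilon: float = FLUX_EPSILON
    fva_confirm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold quantile must be in (0, 1)")
        if not 0 < self.objective_fraction <= 1:
            raise ValueError("objective fraction must be in (0, 1]")
        if self.flux_epsilon <= 0:
            raise ValueError("flux epsilon must be positive")


@dataclass
class GimmeSolution:
    """Penalty-minimal flux state: threshold, penalties, protected set,
    flux vector, inconsistency score Σ c_i·|v_i| and parent optimum Z*."""

    threshold: float
    penalties: dict[str, float]
    protected: set[str]
    fluxes: FluxDistribution
    inconsistency: float
    parent_optimum: float
    objective_fraction: float


@dataclass
class ContextModel:
    """A reduced model plus provenance: which reactions were removed, from
    which parent, under which configuration."""

    model: MetabolicModel
    removed: set[str]
    parent_id: str
    solution: GimmeSolution
    config: GimmeConfig
    weighting: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        return {
            "parent_id": self.parent_id,
            "context_id": self.model.id,
            "removed_reactions": sorted(self.removed),
            "threshold": self.solution.threshold,
            "inconsistency": self.solution.inconsistency,
            "parent_optimum": self.solution.parent_optimum,
            "objective_fraction": self.solution.objective_fraction,
            "threshold_quantile": self.config.threshold_quantile,
            "fva_confirm": self.config.fva_confirm,
            "weighting": self.weighting,
        }

    def provenance_json(self) -> str:
        return json.dumps(self.provenance(), indent=1, sort_keys=True)


def compute_threshold(rexpr: ReactionExpression, quantile: float = 0.25) -> float:
    """Expression threshold t: the given quantile (linear interpolation
    between order statistics) of the data-bearing reaction values;
    NO_DATA reactions are excluded."""
    values = list(rexpr.data_items().values())
    if not values:
        raise ValueError("all reactions are NO_DATA; threshold undefined")
    return float(np.quantile(values, quantile))


def penalty_coefficients(
    rexpr: ReactionExpression, threshold: float
) -> tuple[dict[str, float], set[str]]:
    """Penalties c_i = max(t − x_i, 0) for data-bearing reactions; NO_DATA
    reactions get zero penalty and membership in the protected set."""
    penalties: dict[str, float] = {}
    protected: set[str] = set()
    for rid, value in rexpr.values.items():
        if value is NO_DATA:
            penalties[rid] = 0.0
            protected.add(rid)
        else:
            penalties[rid] = max(threshold - float(value), 0.0)
    return penalties, protected


def gimme_lp(
    model: MetabolicModel,
    penalties: dict[str, float],
    fraction: float = 0.9,
    protected: set[str] | None = None,
    threshold: float = float("nan"),
) -> GimmeSolution:
    """Solve min Σ c_i·|v_i| s.t. S·v = 0, bounds, v_obj >= fraction·Z*.

    |v_i| is realized by splitting each flux into nonnegative forward and
    backward components. The parent FBA must be optimal with Z* > 0.
    """
    parent = fba(model)
    if parent.status != OPTIMAL:
        raise LPError(f"parent model {model.id!r} FBA is {parent.status}")
    if parent.objective_value <= 0:
        raise LPError(
            f"parent optimum {parent.objective_value:g} is not positive; "
            "the objective fraction constraint would be vacuous"
        )
    problem = _LPProblem.from_model(model)
    n = len(problem.reaction_ids)
    c = np.array([penalties.get(rid, 0.0) for rid in problem.reaction_ids])
    if (c < 0).any():
        raise ValueError("penalty coefficients must be nonnegative")
    # v = v+ - v-, both components nonnegative within the original bounds.
    lower = np.concatenate(
        [np.maximum(problem.lower, 0.0), np.maximum(-problem.upper, 0.0)]
    )
    upper = np.concatenate(
        [np.maximum(problem.upper, 0.0), np.maximum(-problem.lower, 0.0)]
    )
    A_eq = sparse.hstack([problem.S, -problem.S], format="csc")
    floor = fraction * parent.objective_value
    obj_row = np.zeros(2 * n)
    obj_row[problem.objective_index] = -1.0
    obj_row[n + problem.objective_index] = 1.0
    result = linprog(
        np.concatenate([c, c]),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=obj_row[None, :],
        b_ub=np.array([-(floor - 1e-9 * max(1.0, abs(floor)))]),
        bounds=list(zip(lower, upper)),
        method="highs",
    )
    status = _LINPROG_STATUS.get(result.status, "infeasible")
    if status != OPTIMAL:
        raise LPError(f"GIMME penalty LP is {status} at fraction {fraction}")
    v = result.x[:n] - result.x[n:]
    fluxes = FluxDistribution(
        fluxes=dict(zip(problem.reaction_ids, map(float, v))),
        objective_value=float(v[problem.objective_index]),
        status=OPTIMAL,
    )
    inconsistency = float(np.dot(c, np.abs(v)))
    return GimmeSolution(
        threshold=threshold,
        penalties={rid: float(ci) for rid, ci in zip(problem.reaction_ids, c)},
        protected=set(protected or ()),
        fluxes=fluxes,
        inconsistency=inconsistency,
        parent_optimum=float(parent.objective_value),
        objective_fraction=float(fraction),
    )


def extract_context_model(
    model: MetabolicModel,
    solution: GimmeSolution,
    config: GimmeConfig = GimmeConfig(),
) -> ContextModel:
    """Remove penalized reactions that carry no flux in the penalty minimum.

    A reaction is removed iff c_i > 0 and |v_i| <= ε; with ``fva_confirm``
    the removal additionally requires the reaction's FVA range at objective
    fraction f to lie within [−ε, ε], making the removed set independent of
    which optimal vertex the solver returned. Protected (NO_DATA) and
    above-threshold reactions are never removed. The reduced model must
    still attain f·Z*, which is re-checked by FBA.
    """
    eps = config.flux_epsilon
    candidates = {
        rid
        for rid, ci in solution.penalties.items()
        if ci > 0
        and rid not in solution.protected
        and abs(solution.fluxes.fluxes[rid]) <= eps
    }
    if config.fva_confirm and candidates:
        ranges = fva(
            model, fraction=solution.objective_fraction, reactions=sorted(candidates)
        ).ranges
        candidates = {
            rid
            for rid in candidates
            if -eps <= ranges[rid][0] and ranges[rid][1] <= eps
        }
    reduced = MetabolicModel(
        id=f"{model.id}_context",
        metabolites=list(model.metabolites),
        reactions=[r.copy() for r in model.reactions if r.id not in candidates],
        objective_reaction=model.objective_reaction,
        genes=set(model.genes),
    )
    check = fba(reduced)
    floor = solution.objective_fraction * solution.parent_optimum
    if check.status != OPTIMAL or check.objective_value < floor - 1e-6:
        raise RuntimeError(
            f"context model lost the objective guarantee: status={check.status}, "
            f"objective={check.objective_value!r} < {floor:g}"
        )
    logger.info(
        "context model %s: removed %d/%d reactions, objective %.6g (floor %.6g)",
        reduced.id, len(candidates), len(model.reactions),
        check.objective_value, floor,
    )
    return ContextModel(
        model=reduced,
        removed=candidates,
        parent_id=model.id,
        solution=solution,
        config=config,
    )


def gimme(
    model: MetabolicModel,
    rexpr: ReactionExpression,
    config: GimmeConfig = GimmeConfig(),
) -> ContextModel:
    """Full GIMME: threshold, penalties, penalty LP, extraction."""
    threshold = compute_threshold(rexpr, config.threshold_quantile)
    penalties, protected = penalty_coefficients(rexpr, threshold)
    solution = gimme_lp(
        model,
        penalties,
        fraction=config.objective_fraction,
        protected=protected,
        threshold=threshold,
    )
    return extract_context_model(model, solution, config)


def ssgsea_gimme(
    model: MetabolicModel,
    expression,
    sets: GeneSetCollection,
    sample: str,
    ssgsea_config: SsgseaConfig = SsgseaConfig(),
    gimme_config: GimmeConfig = GimmeConfig(),
    mode: str = MULTIPLY_POSITIVE_NES,
    combine: str = "max",
    missing_policy: str = IGNORE,
    weighting_enabled: bool = True,
    scores=None,
) -> ContextModel:
    """The combined framework: ssGSEA-weighted expression fed into GIMME.

    With ``weighting_enabled=False`` all gene weights are 1 and the result
    is, by construction, the plain-GIMME context model for the sample.
    Precomputed ``scores`` (an EnrichmentResult for this matrix) can be
    passed to amortize the permutation null across samples.
    """
    profile = expression[sample]
    if weighting_enabled:
        if scores is None:
            scores = ssgsea(expression, sets, ssgsea_config)
        weighted = gene_set_weighting(
            profile, scores, sets, mode=mode, combine=combine, sample=sample
        )
        weighting_info = {
            "enabled": True,
            "mode": mode,
            "combine": combine,
            "n_reweighted_genes": len(weighted.provenance),
            "ssgsea_seed": ssgsea_config.seed,
        }
    else:
        weighted = WeightedExpression.identity(profile)
        weighting_info = {"enabled": False}
    rexpr = reaction_expression(model, weighted, missing_policy)
    context = gimme(model, rexpr, gimme_config)
    context.weighting = weighting_info
    return context
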