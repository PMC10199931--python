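"""Shared fixtures: toy models, synthetic omics data, and test-local oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ssgimme.fixtures import (
    ToyOverflowSpec,
    decoy_genes,
    synthetic_expression,
    synthetic_gene_sets,
    toy_overflow_model,
)


@pytest.fixture
def toy_spec():
    return ToyOverflowSpec()


@pytest.fixture
def toy_model(toy_spec):
    """Default toy overflow model: G=10, O=6 (oxygen-limited)."""
    return toy_overflow_model(toy_spec)


@pytest.fixture
def o2rich_spec():
    return ToyOverflowSpec(oxygen_cap=100.0)


@pytest.fixture
def o2rich_model(o2rich_spec):
    """Oxygen-sufficient variant: respiration alone can carry growth."""
    return toy_overflow_model(o2rich_spec)


@pytest.fixture
def pathway_sets(o2rich_model):
    return synthetic_gene_sets(o2rich_model, scheme="per_pathway")


def respiration_biased_expression(model, sets, seed=7, n_samples=1, noise_sd=0.1):
    """Expression with respiration+transport genes (and their set decoys)
    high, fermentation genes low, over a 30-gene neutral background."""
    extras = tuple(sorted(sets.all_genes() - model.genes)) + tuple(
        f"bg_{i}" for i in range(30)
    )
    active = (
        {"g_resp", "g_transp"}
        | set(decoy_genes("respiration", 2))
        | set(decoy_genes("transport", 2))
    )
    return synthetic_expression(
        model,
        active,
        high=10.0,
        low=1.0,
        noise_sd=noise_sd,
        n_samples=n_samples,
        seed=seed,
        extra_genes=extras,
    )


@pytest.fixture
def biased_expression(o2rich_model, pathway_sets):
    return respiration_biased_expression(o2rich_model, pathway_sets)


# ---------------------------------------------------------------------------
# Test-local oracles (kept independent of the implementation they check)
# ---------------------------------------------------------------------------


def random_gimme_instance(rng):
    """A randomized 8-reaction toy model with random reaction expression
    (some reactions unmeasured), for GIMME oracle-equivalence checks."""
    from ssgimme.integration import ReactionExpression

    spec = ToyOverflowSpec(
        glucose_uptake=float(rng.uniform(2, 15)),
        oxygen_cap=float(rng.uniform(0, 60)),
        respiration_atp_yield=float(rng.uniform(10, 30)),
        fermentation_atp_yield=float(rng.uniform(1, 5)),
        biomass_atp_cost=float(rng.uniform(5, 15)),
    )
    model = toy_overflow_model(spec)
    values = {}
    for reaction in model.reactions:
        if reaction.id == "BIOMASS" or rng.random() < 0.25:
            values[reaction.id] = None  # unmeasured -> protected
        else:
            values[reaction.id] = float(rng.uniform(0.0, 5.0))
    return model, ReactionExpression(values=values)


def brute_force_es(genes_ranked, correlations, gene_set, alpha, statistic):
    """Direct double loop over list positions and genes: the definitional
    running-score computation, no vectorization shared with the package."""
    members = set(gene_set) & set(genes_ranked)
    n = len(genes_ranked)
    n_in = len(members)
    total_w = sum(
        abs(correlations[j]) ** alpha
        for j in range(n)
        if genes_ranked[j] in members
    )
    res = []
    for i in range(1, n + 1):
        p_in = (
            sum(
                abs(correlations[j]) ** alpha
                for j in range(i)
                if genes_ranked[j] in members
            )
            / total_w
        )
        p_out = sum(1 for j in range(i) if genes_ranked[j] not in members) / (n - n_in)
        res.append(p_in - p_out)
    if statistic == "area_under_RES":
        return sum(res)
    return max(res, key=abs)


def cobra_fba_objective(model):
    """Independent FBA route: the same model solved by cobrapy/optlang."""
    from ssgimme.model_io import _to_cobra

    solution = _to_cobra(model).optimize()
    assert solution.status == "optimal"
    return float(solution.objective_value)


def oracle_penalty_minimum(model, penalties, fraction, parent_optimum):
    """min Σ c_i·|v_i| s.t. S·v=0, bounds, v_obj >= fraction·Z*, written
    directly in the test from the LP definition (dense matrices, explicit
    split), or None if infeasible."""
    from scipy.optimize import linprog

    rids = [r.id for r in model.reactions]
    mids = [m.id for m in model.metabolites]
    n = len(rids)
    S = np.zeros((len(mids), n))
    for j, reaction in enumerate(model.reactions):
        for mid, coef in reaction.stoichiometry.items():
            S[mids.index(mid), j] = coef
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.array([penalties.get(rid, 0.0) for rid in rids])
    obj_idx = rids.index(model.objective_reaction)
    A_eq = np.hstack([S, -S])
    bounds = [(max(l, 0.0), max(u, 0.0)) for l, u in zip(lb, ub)] + [
        (max(-u, 0.0), max(-l, 0.0)) for l, u in zip(lb, ub)
    ]
    A_ub = np.zeros((1, 2 * n))
    A_ub[0, obj_idx] = -1.0
    A_ub[0, n + obj_idx] = 1.0
    floor = fraction * parent_optimum
    result = linprog(
        np.concatenate([c, c]),
        A_eq=A_eq,
        b_eq=np.zeros(len(mids)),
        A_ub=A_ub,
        b_ub=[-(floor - 1e-9 * max(1.0, abs(floor)))],
        bounds=bounds,
        method="highs",
    )
    if result.status != 0:
        return None
    return float(result.fun)


def enumerate_removal_minimum(model, penalties, fraction, parent_optimum):
    """Exhaustive search over subsets of penalized reactions: disable each
    subset (bounds 0), keep submodels attaining fraction·Z*, and return the
    minimal achievable inconsistency together with the per-subset values."""
    penalized = sorted(rid for rid, ci in penalties.items() if ci > 0)
    best = None
    per_subset = {}
    for k in range(len(penalized) + 1):
        for subset in itertools.combinations(penalized, k):
            disabled = model.copy()
            index = disabled.reactions_by_id
            for rid in subset:
                index[rid].lower_bound = 0.0
                index[rid].upper_bound = 0.0
            value = oracle_penalty_minimum(
                disabled, penalties, fraction, parent_optimum
            )
            if value is not None:
                per_subset[subset] = value
                if best is None or value < best:
                    best = value
    return best, per_subset
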