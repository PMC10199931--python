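"""Linear-programming analyses on a :class:`~ssgimme.model_io.MetabolicModel`.

FBA maximizes the objective flux subject to steady-state mass balance
S·v = 0 and flux bounds; FVA reports per-reaction flux ranges at a fixed
objective fraction. On top of these sit the chemostat evaluation tools:
uptake sweeps, detection of the critical growth rate μ_crit at which
overflow metabolism (ethanol formation) sets in, reference-normalized
fluxes and the prediction coefficient of determination.

All LPs are solved with HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from ssgimme.model_io import MetabolicModel

logger = logging.getLogger(__name__)

#: Flux activity floor: anything below this is solver noise.
FLUX_EPSILON = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_LINPROG_STATUS = {0: OPTIMAL, 1: INFEASIBLE, 2: INFEASIBLE, 3: UNBOUNDED, 4: INFEASIBLE}


class LPError(RuntimeError):
    """Raised when an LP that must be solvable is not."""


# ---------------------------------------------------------------------------
# Problem assembly
# ---------------------------------------------------------------------------


@dataclass
class _LPProblem:
    """S, bounds and index maps for one model, built once per analysis."""

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: sparse.csc_matrix
    lower: np.ndarray
    upper: np.ndarray
    objective_index: int

    @classmethod
    def from_model(cls, model: MetabolicModel) -> "_LPProblem":
        reaction_ids = [r.id for r in model.reactions]
        metabolite_ids = [m.id for m in model.metabolites]
        met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
        rows, cols, vals = [], [], []
        for j, reaction in enumerate(model.reactions):
            for mid, coef in reaction.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(coef)
        S = sparse.csc_matrix(
            (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
        )
        lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
        upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
        return cls(
            reaction_ids=reaction_ids,
            metabolite_ids=metabolite_ids,
            S=S,
            lower=lower,
            upper=upper,
            objective_index=reaction_ids.index(model.objective_reaction),
        )

    def solve(
        self,
        objective: np.ndarray,
        sense: str = "max",
        extra_ub: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> tuple[str, float, np.ndarray | None]:
        """Optimize ``objective·v`` over {v : S·v=0, bounds, A_ub·v <= b_ub}."""
        c = -objective if sense == "max" else objective
        A_ub = b_ub = None
        if extra_ub is not None:
            A_ub, b_ub = extra_ub
        result = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=list(zip(self.lower, self.upper)),
            method="highs",
        )
        status = _LINPROG_STATUS.get(result.status, INFEASIBLE)
        if status != OPTIMAL:
            return status, math.nan, None
        value = -result.fun if sense == "max" else result.fun
        return OPTIMAL, value, result.x


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------


@dataclass
class FluxDistribution:
    """One flux vector v (mmol·gDW⁻¹·h⁻¹). The biomass pseudoreaction flux
    is read as the specific growth rate μ in h⁻¹. FBA returns one optimal
    vertex: only the objective value and mass balance are solver-independent.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class FvaResult:
    """Per-reaction (min, max) flux at objective >= fraction · optimum."""

    ranges: dict[str, tuple[float, float]]
    objective_fraction: float
    objective_value: float


def fba(model: MetabolicModel) -> FluxDistribution:
    """Flux balance analysis: maximize the objective reaction's flux."""
    problem = _LPProblem.from_model(model)
    objective = np.zeros(len(problem.reaction_ids))
    objective[problem.objective_index] = 1.0
    status, value, x = problem.solve(objective, sense="max")
    if status != OPTIMAL:
        return FluxDistribution(fluxes={}, objective_value=math.nan, status=status)
    return FluxDistribution(
        fluxes=dict(zip(problem.reaction_ids, map(float, x))),
        objective_value=float(value),
        status=OPTIMAL,
    )


def mass_balance_residual(model: MetabolicModel, dist: FluxDistribution) -> float:
    """max |S·v| over metabolites; ~0 for any optimal distribution."""
    problem = _LPProblem.from_model(model)
    v = np.array([dist.fluxes[rid] for rid in problem.reaction_ids])
    return float(np.abs(problem.S @ v).max(initial=0.0))


def _objective_floor_constraint(
    problem: _LPProblem, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    row = np.zeros((1, len(problem.reaction_ids)))
    row[0, problem.objective_index] = -1.0
    return row, np.array([-floor])


def fva(
    model: MetabolicModel,
    fraction: float = 1.0,
    reactions: Sequence[str] | None = None,
) -> FvaResult:
    """Flux variability analysis at ``objective >= fraction * optimum``.

    A tiny relative slack (1e-9) is left on the objective floor so that
    fraction = 1.0 does not go infeasible from solver round-off.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"objective fraction must be in (0, 1], got {fraction}")
    problem = _LPProblem.from_model(model)
    base = np.zeros(len(problem.reaction_ids))
    base[problem.objective_index] = 1.0
    status, optimum, _ = problem.solve(base, sense="max")
    if status != OPTIMAL:
        raise LPError(f"FBA on model {model.id!r} is {status}; FVA undefined")
    floor = fraction * optimum - 1e-9 * max(1.0, abs(optimum))
    constraint = _objective_floor_constraint(problem, floor)
    targets = list(reactions) if reactions is not None else problem.reaction_ids
    index = {rid: i for i, rid in enumerate(problem.reaction_ids)}
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        objective = np.zeros(len(problem.reaction_ids))
        objective[index[rid]] = 1.0
        lo_status, lo, _ = problem.solve(objective, sense="min", extra_ub=constraint)
        hi_status, hi, _ = problem.solve(objective, sense="max", extra_ub=constraint)
        if lo_status != OPTIMAL or hi_status != OPTIMAL:
            raise LPError(f"FVA infeasible at fraction {fraction} for {rid!r}")
        ranges[rid] = (float(min(lo, hi)), float(max(lo, hi)))
    return FvaResult(
        ranges=ranges, objective_fraction=fraction, objective_value=float(optimum)
    )


def sum_variability(result: FvaResult) -> float:
    """Sum of flux-variability interval widths, Σ (max − min)."""
    return float(sum(hi - lo for lo, hi in result.ranges.values()))


# ---------------------------------------------------------------------------
# Chemostat sweep and critical growth rate
# ---------------------------------------------------------------------------


@dataclass
class SweepRow:
    glucose_uptake: float
    growth_rate: float
    exchange_fluxes: dict[str, float]
    status: str = OPTIMAL


@dataclass
class SweepResult:
    """Growth rate and tracked exchange fluxes vs glucose uptake, ordered by
    increasing uptake; ``critical_growth_rate`` is μ at the first grid point
    with ethanol secretion (None when no point ferments or no ethanol
    exchange was tracked)."""

    rows: list[SweepRow] = field(default_factory=list)
    critical_growth_rate: float | None = None

    def to_tsv(self) -> str:
        tracked = sorted(
            {rid for row in self.rows for rid in row.exchange_fluxes}
        )
        lines = ["\t".join(["glucose_uptake", "growth_rate", "status"] + tracked)]
        for row in self.rows:
            cells = [f"{row.glucose_uptake:.10g}", f"{row.growth_rate:.10g}", row.status]
            cells += [f"{row.exchange_fluxes.get(rid, math.nan):.10g}" for rid in tracked]
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def _constrained(
    model: MetabolicModel,
    glucose_exchange: str,
    uptake: float,
    oxygen_exchange: str,
    oxygen_cap: float,
) -> MetabolicModel:
    from ssgimme.model_io import set_exchange_bounds

    # Chemostat operation fixes substrate supply: glucose uptake is an
    # equality (lb = ub = -g); oxygen is capped one-sided.
    return set_exchange_bounds(
        model,
        {
            glucose_exchange: (-uptake, -uptake),
            oxygen_exchange: (-oxygen_cap, 0.0),
        },
    )


def chemostat_sweep(
    model: MetabolicModel,
    glucose_exchange: str,
    uptake_grid: Sequence[float],
    oxygen_exchange: str,
    oxygen_cap: float,
    tracked: Sequence[str] = (),
    ethanol_exchange: str | None = None,
    epsilon: float = FLUX_EPSILON,
) -> SweepResult:
    """Sweep glucose uptake over a grid, maximizing biomass at each point.

    Emulates a glucose-limited chemostat at increasing dilution rate: at each
    grid value g the glucose exchange is fixed to −g, oxygen uptake is capped
    at ``oxygen_cap``, and μ plus the tracked exchange fluxes are recorded.
    Infeasible grid points are flagged and the sweep continues.
    """
    grid = [float(g) for g in uptake_grid]
    if any(g <= 0 for g in grid):
        raise ValueError("uptake grid values must be positive")
    if sorted(grid) != grid:
        raise ValueError("uptake grid must be increasing")
    if oxygen_cap < 0:
        raise ValueError("oxygen cap must be >= 0")
    result = SweepResult()
    for uptake in grid:
        constrained = _constrained(
            model, glucose_exchange, uptake, oxygen_exchange, oxygen_cap
        )
        dist = fba(constrained)
        if dist.status != OPTIMAL:
            logger.warning("sweep point g=%g is %s", uptake, dist.status)
            result.rows.append(
                SweepRow(uptake, math.nan, {rid: math.nan for rid in tracked}, dist.status)
            )
            continue
        result.rows.append(
            SweepRow(
                uptake,
                dist.objective_value,
                {rid: dist.fluxes[rid] for rid in tracked},
                OPTIMAL,
            )
        )
        if (
            ethanol_exchange is not None
            and result.critical_growth_rate is None
            and dist.fluxes.get(ethanol_exchange, 0.0) > epsilon
        ):
            result.critical_growth_rate = dist.objective_value
    return result


def _forced_ethanol(
    model: MetabolicModel,
    glucose_exchange: str,
    uptake: float,
    oxygen_exchange: str,
    oxygen_cap: float,
    ethanol_exchange: str,
) -> tuple[float, float]:
    """(μ, minimum ethanol secretion over all optima) at fixed uptake.

    Using the FVA minimum at objective fraction 1 makes "fermentation
    detected" solver-independent: ethanol is counted only when every optimal
    flux vector secretes it.
    """
    constrained = _constrained(
        model, glucose_exchange, uptake, oxygen_exchange, oxygen_cap
    )
    result = fva(constrained, fraction=1.0, reactions=[ethanol_exchange])
    return result.objective_value, result.ranges[ethanol_exchange][0]


def critical_growth_rate(
    model: MetabolicModel,
    glucose_exchange: str,
    oxygen_exchange: str,
    oxygen_cap: float,
    search_interval: tuple[float, float],
    ethanol_exchange: str,
    tol: float = 1e-4,
    epsilon: float = FLUX_EPSILON,
) -> float | None:
    """μ_crit: the growth rate at the onset of overflow metabolism.

    Bisects on glucose uptake g in ``search_interval`` for the smallest
    uptake at which ethanol secretion is forced (> epsilon) at the biomass
    optimum, and returns μ there. Returns None with a warning when the
    interval does not bracket the onset; if fermentation is already forced
    at the lower end (e.g. oxygen cap 0), returns μ at that end.
    """
    g_lo, g_hi = search_interval
    if not 0 < g_lo < g_hi:
        raise ValueError("search interval must satisfy 0 < g_lo < g_hi")
    mu_lo, eth_lo = _forced_ethanol(
        model, glucose_exchange, g_lo, oxygen_exchange, oxygen_cap, ethanol_exchange
    )
    if eth_lo > epsilon:
        logger.warning(
            "fermentation already forced at g_lo=%g; returning boundary growth rate",
            g_lo,
        )
        return mu_lo
    _, eth_hi = _forced_ethanol(
        model, glucose_exchange, g_hi, oxygen_exchange, oxygen_cap, ethanol_exchange
    )
    if eth_hi <= epsilon:
        logger.warning("no fermentation at g_hi=%g; interval does not bracket", g_hi)
        return None
    while g_hi - g_lo > tol:
        mid = 0.5 * (g_lo + g_hi)
        _, eth_mid = _forced_ethanol(
            model, glucose_exchange, mid, oxygen_exchange, oxygen_cap, ethanol_exchange
        )
        if eth_mid > epsilon:
            g_hi = mid
        else:
            g_lo = mid
    mu_crit, _ = _forced_ethanol(
        model, glucose_exchange, g_hi, oxygen_exchange, oxygen_cap, ethanol_exchange
    )
    return mu_crit


# ---------------------------------------------------------------------------
# Flux comparison metrics
# ---------------------------------------------------------------------------


def normalize_fluxes(
    dist: FluxDistribution, reference: str, epsilon: float = FLUX_EPSILON
) -> dict[str, float]:
    """Fluxes relative to a reference reaction (e.g. hexokinase, so that
    v_ref^rel = 1); errors when the reference carries ~zero flux."""
    ref = dist.fluxes[reference]
    if abs(ref) <= epsilon:
        raise ValueError(
            f"reference reaction {reference!r} carries no flux ({ref:g}); "
            "cannot normalize"
        )
    return {rid: v / ref for rid, v in dist.fluxes.items()}


def prediction_r2(
    predicted: Mapping[str, float],
    measured: Mapping[str, float],
    method: str = "sse",
) -> float:
    """Coefficient of determination of predicted vs measured fluxes.

    ``method="sse"`` (default): R² = 1 − Σ(meas−pred)² / Σ(meas−mean)²,
    computed over the common ids; can be negative for predictions worse
    than the measured mean, which squared correlation would hide.
    ``method="pearson"``: squared Pearson correlation, for comparison.
    """
    common = sorted(set(predicted) & set(measured))
    if len(common) < 2:
        raise ValueError(f"need >= 2 common ids, got {len(common)}")
    y = np.array([measured[k] for k in common], dtype=float)
    yhat = np.array([predicted[k] for k in common], dtype=float)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst <= 0:
        raise ValueError("measured values have zero variance")
    if method == "sse":
        return 1.0 - float(((y - yhat) ** 2).sum()) / sst
    if method == "pearson":
        if float(((yhat - yhat.mean()) ** 2).sum()) <= 0:
            raise ValueError("predicted values have zero variance")
        return float(np.corrcoef(y, yhat)[0, 1] ** 2)
    raise ValueError(f"unknown method {method!r}")


def fva_tsv(result: FvaResult) -> str:
    lines = ["reaction\tmin_flux\tmax_flux"]
    for rid, (lo, hi) in result.ranges.items():
        lines.append(f"{rid}\t{lo:.10g}\t{hi:.10g}")
    return "\n".join(lines) + "\n"
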