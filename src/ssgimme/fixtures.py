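"""Deterministic toy models and synthetic omics data.

The central fixture is an 8-reaction lumped model of yeast energy
metabolism with two ATP-generating routes — respiration (high yield,
oxygen-limited) and fermentation to ethanol (low yield) — whose FBA optima
have closed forms. It reproduces, at desk scale, the overflow-metabolism
(Crabtree) behaviour of glucose-limited chemostats: fully respiratory
growth below a critical growth rate, ethanol secretion above it.

Stoichiometry (carbon-balanced; glucose is 6C, ethanol 2C):

    respiration:   glc + 6 o2 -> 6 co2 + 26 atp
    fermentation:  glc -> 2 etoh + 2 co2 + 2 atp
    biomass:       10 atp -> (growth, flux = μ)

With glucose uptake G and oxygen cap O, respiration flux is min(G, O/6),
so μ = (2·G + 24·min(G, O/6)) / 10, ethanol appears at uptake g* = O/6,
and the critical growth rate is μ_crit = 26·(O/6)/10 = 13·O/30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ssgimme.enrichment import GeneSetCollection
from ssgimme.model_io import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
)

RESPIRATION_GENE = "g_resp"
FERMENTATION_GENE = "g_ferm"
TRANSPORT_GENE = "g_transp"


@dataclass(frozen=True)
class ToyOverflowSpec:
    """Parameters of the toy overflow model and its closed-form optima."""

    glucose_uptake: float = 10.0
    oxygen_cap: float = 6.0
    respiration_atp_yield: float = 26.0
    fermentation_atp_yield: float = 2.0
    biomass_atp_cost: float = 10.0

    def __post_init__(self) -> None:
        if self.glucose_uptake <= 0:
            raise ValueError("glucose uptake must be positive")
        if self.oxygen_cap < 0:
            raise ValueError("oxygen cap must be >= 0")

    def optimal_growth(self) -> float:
        """Closed-form FBA optimum μ = (2G + 24·min(G, O/6)) / 10."""
        respired = min(self.glucose_uptake, self.oxygen_cap / 6.0)
        return (
            self.fermentation_atp_yield * self.glucose_uptake
            + (self.respiration_atp_yield - self.fermentation_atp_yield) * respired
        ) / self.biomass_atp_cost

    def overflow_onset(self) -> float:
        """Glucose uptake g* = O/6 above which fermentation is forced."""
        return self.oxygen_cap / 6.0

    def critical_growth_rate(self) -> float:
        """μ_crit = 13·O/30 with the default yields."""
        return (
            self.respiration_atp_yield * self.overflow_onset() / self.biomass_atp_cost
        )


def toy_overflow_model(spec: ToyOverflowSpec | None = None) -> MetabolicModel:
    """Build the 8-reaction / 6-metabolite / 3-gene overflow model.

    Exchanges follow the COBRA sign convention (negative flux = uptake):
    the glucose exchange is bounded at (−G, 0) and the oxygen exchange at
    (−O, 0); an infinite oxygen cap yields an unconstrained respiration
    route. The biomass pseudoreaction drains 10 ATP per unit growth and is
    the objective.
    """
    spec = spec or ToyOverflowSpec()
    inf = math.inf
    o2_lb = -spec.oxygen_cap if math.isfinite(spec.oxygen_cap) else -inf
    metabolites = [
        Metabolite("glc_e", name="D-glucose (extracellular)", compartment="e"),
        Metabolite("glc_c", name="D-glucose", compartment="c"),
        Metabolite("o2_c", name="oxygen", compartment="c"),
        Metabolite("co2_c", name="carbon dioxide", compartment="c"),
        Metabolite("etoh_c", name="ethanol", compartment="c"),
        Metabolite("atp_c", name="ATP", compartment="c"),
    ]
    reactions = [
        Reaction(
            "EX_glc", {"glc_e": -1.0},
            lower_bound=-spec.glucose_uptake, upper_bound=0.0,
            name="D-glucose exchange",
        ),
        Reaction(
            "EX_o2", {"o2_c": -1.0},
            lower_bound=o2_lb, upper_bound=0.0, name="oxygen exchange",
        ),
        Reaction(
            "EX_etoh", {"etoh_c": -1.0},
            lower_bound=0.0, upper_bound=inf, name="ethanol exchange",
        ),
        Reaction(
            "EX_co2", {"co2_c": -1.0},
            lower_bound=0.0, upper_bound=inf, name="carbon dioxide exchange",
        ),
        Reaction(
            "GLCt", {"glc_e": -1.0, "glc_c": 1.0},
            lower_bound=0.0, upper_bound=inf, name="glucose transport",
            gpr=parse_gpr(TRANSPORT_GENE),
        ),
        Reaction(
            "RESP",
            {
                "glc_c": -1.0,
                "o2_c": -6.0,
                "co2_c": 6.0,
                "atp_c": spec.respiration_atp_yield,
            },
            lower_bound=0.0, upper_bound=inf, name="respiration (lumped)",
            gpr=parse_gpr(RESPIRATION_GENE),
        ),
        Reaction(
            "FERM",
            {
                "glc_c": -1.0,
                "etoh_c": 2.0,
                "co2_c": 2.0,
                "atp_c": spec.fermentation_atp_yield,
            },
            lower_bound=0.0, upper_bound=inf, name="fermentation (lumped)",
            gpr=parse_gpr(FERMENTATION_GENE),
        ),
        Reaction(
            "BIOMASS", {"atp_c": -spec.biomass_atp_cost},
            lower_bound=0.0, upper_bound=inf, name="biomass pseudoreaction",
        ),
    ]
    return MetabolicModel(
        id="toy_overflow",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction="BIOMASS",
    )


def synthetic_expression(
    model: MetabolicModel,
    active_genes: set[str],
    high: float = 10.0,
    low: float = 1.0,
    noise_sd: float = 0.1,
    n_samples: int = 1,
    seed: int = 0,
    extra_genes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Synthetic expression matrix (genes × samples), pre-normalized scale.

    Active genes center on ``high``, the rest on ``low``, with
    multiplicative lognormal noise of log-scale sd ``noise_sd``; with
    ``noise_sd=0`` the values are exact. ``extra_genes`` adds rows beyond
    the model's genes (decoys/background for gene-set tests).
    """
    if not high > low >= 0:
        raise ValueError("need high > low >= 0")
    if n_samples < 1:
        raise ValueError("need n_samples >= 1")
    universe = sorted(model.genes) + [g for g in extra_genes if g not in model.genes]
    unknown = set(active_genes) - set(universe)
    if unknown:
        raise KeyError(f"active genes not in model or extras: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = np.array([high if g in active_genes else low for g in universe])
    values = base[:, None] * np.exp(
        rng.normal(0.0, noise_sd, size=(len(universe), n_samples))
    )
    return pd.DataFrame(
        values,
        index=pd.Index(universe, name="gene"),
        columns=[f"sample_{i + 1}" for i in range(n_samples)],
    )


#: Pathway label per toy reaction with a gene association.
_TOY_PATHWAYS = {"RESP": "respiration", "FERM": "fermentation", "GLCt": "transport"}


def decoy_genes(pathway: str, count: int) -> list[str]:
    return [f"dec_{pathway}_{i + 1}" for i in range(count)]


def synthetic_gene_sets(
    model: MetabolicModel,
    scheme: str = "per_pathway",
    seed: int = 0,
    min_set_size: int = 3,
) -> GeneSetCollection:
    """Gene sets standing in for a curated metabolic-process annotation.

    ``per_pathway``: one set per gene-associated pathway (respiration,
    fermentation, transport on the toy model), padded with decoy genes to
    reach ``min_set_size``; decoys live only in the expression matrix, not
    in any GPR, so flux optima are untouched. ``random``: size-matched sets
    drawn uniformly from the same gene universe.
    """
    if not model.genes:
        raise ValueError("model has no genes")
    pathway_genes: dict[str, list[str]] = {}
    for reaction in model.reactions:
        genes = sorted(reaction.gpr.genes())
        if not genes:
            continue
        name = _TOY_PATHWAYS.get(reaction.id, reaction.id)
        pathway_genes.setdefault(name, [])
        pathway_genes[name].extend(g for g in genes if g not in pathway_genes[name])
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for name, genes in sorted(pathway_genes.items()):
        padded = list(genes) + decoy_genes(name, max(0, min_set_size - len(genes)))
        sets[name] = (f"{name} pathway", tuple(padded))
    if scheme == "per_pathway":
        return GeneSetCollection(sets)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        universe = sorted({g for _, genes in sets.values() for g in genes})
        random_sets = {
            f"random_{name}": (
                "random size-matched set",
                tuple(rng.choice(universe, size=len(genes), replace=False)),
            )
            for name, (_, genes) in sets.items()
        }
        return GeneSetCollection(random_sets)
    raise ValueError(f"unknown scheme {scheme!r}")
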