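"""Constraint-based metabolic models: domain types, GPR rule algebra, and I/O.

A :class:`MetabolicModel` is the in-memory form of a constraint-based
reconstruction: metabolites (rows of the stoichiometric matrix S), reactions
(columns of S, each with flux bounds in mmol·gDW⁻¹·h⁻¹ and a boolean
gene-protein-reaction rule), and a biomass-style objective reaction whose
flux proxies the specific growth rate μ.

SBML Level 3 + fbc files are read and written through cobrapy/libsbml; a
lightweight JSON dialect (documented in :func:`read_json_model`) covers
desk-scale fixtures without an SBML toolchain.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple


class GPRSyntaxError(ValueError):
    """Raised for malformed GPR rule text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ModelValidationError(ValueError):
    """Raised when a model or an operation on it violates a type invariant."""


class ModelIOError(ValueError):
    """Raised when a model file cannot be parsed or written."""


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------

GENE = "GENE"
AND = "AND"
OR = "OR"
EMPTY = "EMPTY"


@dataclass(frozen=True)
class GPRTree:
    """Boolean gene-protein-reaction rule.

    ``AND`` nodes represent enzyme complexes (every subunit required),
    ``OR`` nodes isozymes (any one suffices). Leaves are ``GENE`` nodes;
    ``EMPTY`` stands for a reaction with no gene association and occurs
    only as a whole rule.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRTree", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == GENE:
            if not self.gene:
                raise ModelValidationError("GENE node requires a gene id")
        elif self.kind in (AND, OR):
            if len(self.children) < 2:
                raise ModelValidationError(f"{self.kind} node requires >= 2 children")
        elif self.kind == EMPTY:
            if self.gene or self.children:
                raise ModelValidationError("EMPTY node carries no payload")
        else:
            raise ModelValidationError(f"unknown GPR node kind {self.kind!r}")

    @property
    def is_empty(self) -> bool:
        return self.kind == EMPTY

    def genes(self) -> set[str]:
        """All gene ids appearing in the rule."""
        if self.kind == GENE:
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def to_string(self) -> str:
        """Normalized rule text; ``parse_gpr`` round-trips it exactly."""
        if self.kind == EMPTY:
            return ""
        if self.kind == GENE:
            return self.gene  # type: ignore[return-value]
        sep = " and " if self.kind == AND else " or "
        parts = []
        for child in self.children:
            text = child.to_string()
            # `and` binds tighter than `or`: an OR child under AND needs parens.
            if self.kind == AND and child.kind == OR:
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


def gpr_gene(gene_id: str) -> GPRTree:
    return GPRTree(GENE, gene=gene_id)


def gpr_empty() -> GPRTree:
    return GPRTree(EMPTY)


def _flatten(kind: str, children: Iterable[GPRTree]) -> GPRTree:
    flat: list[GPRTree] = []
    for child in children:
        if child.kind == kind:
            flat.extend(child.children)
        else:
            flat.append(child)
    if len(flat) == 1:
        return flat[0]
    return GPRTree(kind, children=tuple(flat))


_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|([^\s()]+))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.end() == pos:
            break
        start = match.start(match.lastindex)  # type: ignore[arg-type]
        if match.group(1):
            tokens.append(("LPAR", "(", start))
        elif match.group(2):
            tokens.append(("RPAR", ")", start))
        else:
            word = match.group(3)
            low = word.lower()
            if low in ("and", "or"):
                tokens.append((low.upper(), word, start))
            else:
                tokens.append(("ID", word, start))
        pos = match.end()
    tokens.append(("END", "", len(text)))
    return tokens


class _GprParser:
    """Recursive-descent parser: ``or`` < ``and`` < atom; n-ary flattening."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.index]

    def advance(self) -> tuple[str, str, int]:
        token = self.tokens[self.index]
        self.index += 1
        return token

    def parse(self) -> GPRTree:
        tree = self.parse_or()
        kind, value, pos = self.peek()
        if kind != "END":
            raise GPRSyntaxError(f"unexpected {value!r}", pos)
        return tree

    def parse_or(self) -> GPRTree:
        children = [self.parse_and()]
        while self.peek()[0] == "OR":
            self.advance()
            children.append(self.parse_and())
        return _flatten(OR, children)

    def parse_and(self) -> GPRTree:
        children = [self.parse_atom()]
        while self.peek()[0] == "AND":
            self.advance()
            children.append(self.parse_atom())
        return _flatten(AND, children)

    def parse_atom(self) -> GPRTree:
        kind, value, pos = self.advance()
        if kind == "ID":
            return gpr_gene(value)
        if kind == "LPAR":
            tree = self.parse_or()
            closing, _, close_pos = self.advance()
            if closing != "RPAR":
                raise GPRSyntaxError("unbalanced parenthesis", close_pos)
            return tree
        if kind in ("AND", "OR"):
            raise GPRSyntaxError(f"dangling operator {value!r}", pos)
        if kind == "RPAR":
            raise GPRSyntaxError("unbalanced parenthesis", pos)
        raise GPRSyntaxError("unexpected end of rule", pos)


def parse_gpr(rule_text: str) -> GPRTree:
    """Parse GPR rule text into a :class:`GPRTree`.

    Grammar: case-insensitive ``and``/``or`` keywords, parentheses, gene ids
    as bare words; ``and`` binds tighter than ``or``; same-operator chains
    are flattened into one n-ary node. An empty (or all-whitespace) rule
    yields the ``EMPTY`` tree.
    """
    if not rule_text or not rule_text.strip():
        return gpr_empty()
    return _GprParser(rule_text).parse()


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be nonempty")


@dataclass
class Reaction:
    """One column of S: stoichiometry (negative = consumed), flux bounds
    in mmol·gDW⁻¹·h⁻¹, and a GPR rule. Exchange reactions are the boundary
    columns touching exactly one metabolite; by the standard sign
    convention a negative exchange flux is uptake, a positive one secretion.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""
    gpr: GPRTree = field(default_factory=gpr_empty)

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be nonempty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
            gpr=self.gpr,
        )


@dataclass
class MetabolicModel:
    """A constraint-based model: S, bounds, GPRs and the objective reaction."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.genes = set(self.genes) | self.gpr_genes()
        self.validate()

    # -- lookups ----------------------------------------------------------

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def metabolites_by_id(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions_by_id[reaction_id]
        except KeyError:
            raise KeyError(f"no reaction {reaction_id!r} in model {self.id!r}")

    def gpr_genes(self) -> set[str]:
        out: set[str] = set()
        for reaction in self.reactions:
            out |= reaction.gpr.genes()
        return out

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError(f"model {self.id!r}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError(f"model {self.id!r}: duplicate reaction ids")
        known = set(met_ids)
        for reaction in self.reactions:
            missing = set(reaction.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {reaction.id!r} references unknown metabolites "
                    f"{sorted(missing)}"
                )
        if self.objective_reaction not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        if not self.genes >= self.gpr_genes():
            raise ModelValidationError("model gene set does not cover GPR genes")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            objective_reaction=self.objective_reaction,
            genes=set(self.genes),
        )


class ModelSummary(NamedTuple):
    n_reactions: int
    n_metabolites: int
    n_genes: int


def model_summary(model: MetabolicModel) -> ModelSummary:
    """Counts of reactions, metabolites and genes (e.g. 4058/2742/1150 for
    the consensus yeast model v8.4.2)."""
    return ModelSummary(len(model.reactions), len(model.metabolites), len(model.genes))


def summary_tsv(model: MetabolicModel) -> str:
    counts = model_summary(model)
    return (
        "model\treactions\tmetabolites\tgenes\n"
        f"{model.id}\t{counts.n_reactions}\t{counts.n_metabolites}\t{counts.n_genes}\n"
    )


def set_exchange_bounds(
    model: MetabolicModel, constraints: Mapping[str, tuple[float, float]]
) -> MetabolicModel:
    """Return a copy with new bounds on the named exchange reactions.

    Every other bound keeps the model's original value. Uptake is encoded as
    a negative lower bound on the exchange flux, so fixing a measured uptake
    rate ``u`` means ``constraints[rid] = (-u, 0)`` (or ``(-u, -u)`` for an
    equality, as in a chemostat sweep).
    """
    out = model.copy()
    index = out.reactions_by_id
    for reaction_id, (lower, upper) in constraints.items():
        if reaction_id not in index:
            raise KeyError(f"no reaction {reaction_id!r} in model {model.id!r}")
        reaction = index[reaction_id]
        if not reaction.is_exchange:
            raise ModelValidationError(
                f"reaction {reaction_id!r} is not an exchange reaction"
            )
        if lower > upper:
            raise ModelValidationError(
                f"exchange {reaction_id!r}: lower {lower} exceeds upper {upper}"
            )
        reaction.lower_bound = float(lower)
        reaction.upper_bound = float(upper)
    return out


# ---------------------------------------------------------------------------
# SBML I/O (through cobrapy / libsbml)
# ---------------------------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.id or "model")
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in model.metabolites
    }
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for reaction in model.reactions:
        crxn = cobra.Reaction(
            reaction.id,
            name=reaction.name,
            lower_bound=reaction.lower_bound,
            upper_bound=reaction.upper_bound,
        )
        crxns.append(crxn)
    cmodel.add_reactions(crxns)
    for reaction, crxn in zip(model.reactions, crxns):
        crxn.add_metabolites(
            {cmets[mid]: coef for mid, coef in reaction.stoichiometry.items()}
        )
        if not reaction.gpr.is_empty:
            crxn.gene_reaction_rule = reaction.gpr.to_string()
    cmodel.objective = model.objective_reaction
    return cmodel


def _from_cobra(cmodel, model_id: str | None = None) -> MetabolicModel:
    metabolites = [
        Metabolite(m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cmodel.metabolites
    ]
    reactions = []
    objective_id = None
    for crxn in cmodel.reactions:
        if crxn.objective_coefficient:
            objective_id = crxn.id
        reactions.append(
            Reaction(
                id=crxn.id,
                name=crxn.name or "",
                stoichiometry={m.id: float(c) for m, c in crxn.metabolites.items()},
                lower_bound=float(crxn.lower_bound),
                upper_bound=float(crxn.upper_bound),
                gpr=parse_gpr(crxn.gene_reaction_rule or ""),
            )
        )
    if objective_id is None:
        raise ModelValidationError(
            f"model {cmodel.id!r} declares no objective reaction"
        )
    return MetabolicModel(
        id=model_id or cmodel.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective_reaction=objective_id,
        genes={g.id for g in cmodel.genes},
    )


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML Level 3 + fbc model (bounds, objective, GPR strings).

    Raises :class:`ModelIOError` for unparsable files and
    :class:`ModelValidationError` when the content violates a model
    invariant (e.g. no fbc objective).
    """
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(path)
    except ModelValidationError:
        raise
    except Exception as exc:  # cobra raises a zoo of types for bad SBML
        raise ModelIOError(f"cannot parse SBML file {path!r}: {exc}") from exc
    return _from_cobra(cmodel)


def write_model(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 + fbc; round-trips through
    :func:`read_sbml` to a structurally identical model."""
    import cobra.io

    cobra.io.write_sbml_model(_to_cobra(model), path)


# ---------------------------------------------------------------------------
# JSON fixture dialect
# ---------------------------------------------------------------------------
#
# Schema:
# {
#   "id": str,
#   "objective_reaction": str,
#   "metabolites": [{"id": str, "name": str?, "compartment": str?}, ...],
#   "reactions": [{"id": str, "name": str?,
#                  "stoichiometry": {met_id: coefficient, ...},
#                  "lower_bound": num, "upper_bound": num,
#                  "gpr": str?}, ...],
#   "genes": [str, ...]?          # optional extras beyond GPR genes
# }


def read_json_model(path: str) -> MetabolicModel:
    """Read the lightweight JSON model dialect (schema above)."""
    with open(path) as handle:
        payload = json.load(handle)
    return model_from_dict(payload)


def write_json_model(model: MetabolicModel, path: str) -> None:
    with open(path, "w") as handle:
        json.dump(model_to_dict(model), handle, indent=1, sort_keys=True)
        handle.write("\n")


def model_from_dict(payload: Mapping) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                m["id"], name=m.get("name", ""), compartment=m.get("compartment", "c")
            )
            for m in payload["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", 0.0)),
                upper_bound=float(r.get("upper_bound", 1000.0)),
                gpr=parse_gpr(r.get("gpr", "")),
            )
            for r in payload["reactions"]
        ]
        return MetabolicModel(
            id=payload.get("id", "model"),
            metabolites=metabolites,
            reactions=reactions,
            objective_reaction=payload["objective_reaction"],
            genes=set(payload.get("genes", ())),
        )
    except KeyError as exc:
        raise ModelIOError(f"JSON model missing required field {exc}") from exc


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "objective_reaction": model.objective_reaction,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
    }
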