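"""Core data structures of a constraint-based metabolic model.

A :class:`MetabolicModel` holds metabolites, reactions, genes, the linear
objective and the compartment set, and yields the stoichiometric matrix S
(rows = metabolites, columns = reactions) used by flux balance analysis:
maximise c'v subject to S v = 0 and lb <= v <= ub, with fluxes in
mmol/gDCW/h and the biomass flux in 1/h.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import sparse

from .gpr import EMPTY_RULE, GPRRule

REACTION_KINDS = ("metabolic", "transport", "exchange", "spontaneous", "biomass")

# conventional COBRA "infinity" proxy for unbounded fluxes (mmol/gDCW/h)
DEFAULT_BOUND = 1000.0

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelStructureError(ValueError):
    """A dangling reference or violated structural invariant."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula in Hill notation into element -> count.

    Accepts generic one/two-letter element symbols (models commonly use
    placeholder symbols for carrier moieties). Raises ValueError on text
    that is not a sequence of ``El[count]`` tokens.
    """
    if formula is None:
        raise ValueError("formula is None")
    text = formula.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"invalid formula {formula!r} at position {pos}")
        element, digits = m.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def formula_carbon_count(formula: Optional[str]) -> Optional[int]:
    if not formula:
        return None
    try:
        return parse_formula(formula).get("C", 0)
    except ValueError:
        return None


@dataclass
class Metabolite:
    """A chemical species in one compartment (id convention ``name_c``/``name_e``)."""

    id: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    compartment: str = "c"

    def elements(self) -> Optional[Dict[str, int]]:
        if self.formula is None or self.formula == "":
            return None
        return parse_formula(self.formula)


@dataclass
class Gene:
    id: str
    name: Optional[str] = None


@dataclass
class Reaction:
    """A (pseudo-)reaction: stoichiometry, flux bounds and gene association.

    ``stoichiometry`` maps metabolite id -> coefficient (negative = consumed).
    Bounds are mmol/gDCW/h; reversible means lb < 0 < ub.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRRule = EMPTY_RULE
    subsystem: Optional[str] = None
    kind: str = "metabolic"

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"reaction {self.id}: unknown kind {self.kind!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        return self.kind == "exchange"

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    def validate(self):
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id}: lower bound {self.lower_bound} > upper bound {self.upper_bound}"
            )
        for met, coeff in self.stoichiometry.items():
            if coeff == 0:
                raise ModelStructureError(f"reaction {self.id}: zero coefficient for {met}")
        if self.kind == "exchange" and len(self.stoichiometry) != 1:
            raise ModelStructureError(
                f"exchange reaction {self.id} must touch exactly one metabolite, "
                f"touches {len(self.stoichiometry)}"
            )


def infer_reaction_kind(rxn: Reaction, model: Optional["MetabolicModel"] = None) -> str:
    """Heuristic kind for files that do not declare one.

    Single-metabolite stoichiometry or an ``EX_``/``DM_``/``SK_`` prefix means
    exchange; a reaction moving species between compartments is a transport;
    everything else is metabolic.
    """
    if len(rxn.stoichiometry) == 1 or rxn.id.startswith(("EX_", "DM_", "SK_")):
        return "exchange"
    if model is not None:
        comps = set()
        for mid in rxn.stoichiometry:
            met = model.metabolites.get(mid)
            if met is not None:
                comps.add(met.compartment)
        if len(comps) > 1:
            return "transport"
    return "metabolic"


class MetabolicModel:
    """An ordered collection of metabolites, reactions and genes.

    Reaction and metabolite order is preserved (it defines the row/column
    order of S and makes all downstream analyses deterministic).
    """

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Iterable[Gene] = (),
        objective: Optional[Dict[str, float]] = None,
        compartments: Optional[Dict[str, str]] = None,
    ):
        self.id = model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.genes: Dict[str, Gene] = {}
        self.objective: Dict[str, float] = dict(objective or {})
        self.compartments: Dict[str, str] = dict(compartments or {})
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        for g in genes:
            self.add_gene(g)

    # -- construction -------------------------------------------------------
    def add_metabolite(self, met: Metabolite):
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met
        self.compartments.setdefault(met.compartment, met.compartment)

    def add_gene(self, gene: Gene):
        if gene.id not in self.genes:
            self.genes[gene.id] = gene

    def add_reaction(self, rxn: Reaction, register_genes: bool = True):
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id}")
        self.reactions[rxn.id] = rxn
        if register_genes:
            for gid in rxn.gpr.genes():
                self.add_gene(Gene(gid))

    def remove_reaction(self, rxn_id: str):
        self.reactions.pop(rxn_id)
        self.objective.pop(rxn_id, None)

    # -- views --------------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> List[str]:
        return list(self.metabolites)

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def exchange_metabolite(self, rxn: Reaction) -> Metabolite:
        (mid,) = rxn.stoichiometry
        return self.metabolites[mid]

    def reactions_for_gene(self, gene_id: str) -> List[str]:
        return [r.id for r in self.reactions.values() if gene_id in r.gpr.genes()]

    def biomass_reaction_id(self) -> Optional[str]:
        for r in self.reactions.values():
            if r.kind == "biomass":
                return r.id
        for rid, w in self.objective.items():
            if w:
                return rid
        return None

    # -- invariants ----------------------------------------------------------
    def validate(self):
        """Check every structural invariant; raise ModelStructureError listing ids."""
        dangling_mets = sorted(
            {
                mid
                for r in self.reactions.values()
                for mid in r.stoichiometry
                if mid not in self.metabolites
            }
        )
        if dangling_mets:
            raise ModelStructureError(
                "reactions reference undeclared metabolites: " + ", ".join(dangling_mets)
            )
        dangling_genes = sorted(
            {
                gid
                for r in self.reactions.values()
                for gid in r.gpr.genes()
                if gid not in self.genes
            }
        )
        if dangling_genes:
            raise ModelStructureError(
                "GPRs reference undeclared genes: " + ", ".join(dangling_genes)
            )
        bad_obj = sorted(set(self.objective) - set(self.reactions))
        if bad_obj:
            raise ModelStructureError(
                "objective references missing reactions: " + ", ".join(bad_obj)
            )
        for met in self.metabolites.values():
            if met.formula:
                try:
                    parse_formula(met.formula)
                except ValueError as exc:
                    raise ModelStructureError(f"metabolite {met.id}: {exc}") from exc
        for rxn in self.reactions.values():
            rxn.validate()

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            model_id=self.id,
            metabolites=[replace(m) for m in self.metabolites.values()],
            reactions=[r.copy() for r in self.reactions.values()],
            genes=[replace(g) for g in self.genes.values()],
            objective=dict(self.objective),
            compartments=dict(self.compartments),
        )

    def summary(self) -> Dict[str, int]:
        return {
            "genes": len(self.genes),
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
        }

    def __repr__(self) -> str:  # pragma: no cover
        s = self.summary()
        return (
            f"<MetabolicModel {self.id}: {s['reactions']} reactions, "
            f"{s['metabolites']} metabolites, {s['genes']} genes>"
        )


def build_stoichiometric_matrix(
    model: MetabolicModel,
) -> Tuple[sparse.csr_matrix, Dict[str, int], Dict[str, int]]:
    """Assemble S with rows = metabolites, columns = reactions.

    Returns ``(S, metabolite_index, reaction_index)``; S[i, j] is the
    coefficient of metabolite i in reaction j.
    """
    met_index = {mid: i for i, mid in enumerate(model.metabolites)}
    rxn_index = {rid: j for j, rid in enumerate(model.reactions)}
    rows, cols, vals = [], [], []
    for rid, rxn in model.reactions.items():
        j = rxn_index[rid]
        for mid, coeff in rxn.stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_index), len(rxn_index))
    )
    return S, met_index, rxn_index
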