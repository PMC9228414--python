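"""Curation quality control for stoichiometric models.

Checks mirror the manual-refinement stage of a genome-scale
reconstruction: elemental/charge balance with proton/water repair
proposals, duplicate reactions, dead-end and orphan metabolites, blocked
reactions, and thermodynamic directionality assignment from standard
transformed Gibbs energies (reactions are presumed reversible unless
|dG°'| exceeds a 30 kJ/mol threshold at 25 °C, 1 bar, pH 7, 1 mM).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .fba import InfeasibleMediumError, Medium, apply_medium, flux_variability, solve_fba
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

log = logging.getLogger(__name__)

BLOCKED_TOL = 1e-7


# ---------------------------------------------------------------------------
# elemental & charge balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceFinding:
    """Balance audit of one reaction; imbalances are products minus substrates."""

    reaction_id: str
    element_imbalance: Dict[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0
    status: str = "balanced"  # balanced | imbalanced | indeterminate
    proposed_fix: Optional[List[Tuple[str, str, int]]] = None  # (side, species, count)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


@dataclass(frozen=True)
class DirectionalityRule:
    """Gibbs-energy threshold for constraining reaction direction."""

    threshold_kj_per_mol: float = 30.0
    conditions: str = "25 C, 1 bar, pH 7.0, 1 mM"

    def __post_init__(self):
        if self.threshold_kj_per_mol <= 0:
            raise ValueError("directionality threshold must be positive")


def _reaction_imbalance(model: MetabolicModel, rxn: Reaction):
    """(element imbalance, charge imbalance, determinate?) for one reaction."""
    elements: Dict[str, float] = {}
    charge = 0.0
    determinate = True
    for mid, coeff in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        comp = met.elements()
        if comp is None or met.charge is None:
            determinate = False
            continue
        for el, n in comp.items():
            elements[el] = elements.get(el, 0.0) + coeff * n
        charge += coeff * met.charge
    elements = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    return elements, charge, determinate


def check_balance(model: MetabolicModel, include_exchanges: bool = False) -> List[BalanceFinding]:
    """One finding per non-exchange reaction (exchanges are inherently open)."""
    findings = []
    for rxn in model.reactions.values():
        if rxn.kind == "exchange" and not include_exchanges:
            continue
        elements, charge, determinate = _reaction_imbalance(model, rxn)
        if not determinate:
            status = "indeterminate"
        elif not elements and abs(charge) < 1e-9:
            status = "balanced"
        else:
            status = "imbalanced"
        finding = BalanceFinding(
            reaction_id=rxn.id,
            element_imbalance=elements,
            charge_imbalance=charge,
            status=status,
        )
        if status == "imbalanced":
            finding.proposed_fix = _solve_proton_water_fix(model, finding)
        findings.append(finding)
    return findings


def _find_species(model: MetabolicModel, formulas: Sequence[str], compartment: str):
    for comp in (compartment, "c"):
        for met in model.metabolites.values():
            if met.formula in formulas and met.compartment == comp:
                return met
    for met in model.metabolites.values():
        if met.formula in formulas:
            return met
    return None


def _solve_proton_water_fix(model: MetabolicModel, finding: BalanceFinding):
    """Express the imbalance as protons/water added to one side, if possible.

    Solves the small linear system over {H+ (formula H, charge as declared in
    the model, canonically +1), H2O}: water count is fixed by the O imbalance
    and the proton count by the remaining H; charge must then agree. Returns
    a fix list [(side, species, count), ...] or None.
    """
    imb = finding.element_imbalance
    if any(el not in ("H", "O") for el in imb):
        return None
    rxn = model.reactions[finding.reaction_id]
    comp = next(
        (model.metabolites[m].compartment for m in rxn.stoichiometry), "c"
    )
    proton = _find_species(model, ("H",), comp)
    water = _find_species(model, ("H2O",), comp)
    proton_charge = proton.charge if proton is not None and proton.charge is not None else 1

    imb_h = imb.get("H", 0.0)
    imb_o = imb.get("O", 0.0)
    net_water = -imb_o  # added to products (negative = to substrates)
    net_proton = -imb_h - 2 * net_water
    for value in (net_water, net_proton):
        if abs(value - round(value)) > 1e-9:
            return None
    net_water, net_proton = int(round(net_water)), int(round(net_proton))
    if abs(finding.charge_imbalance + net_proton * proton_charge) > 1e-9:
        return None
    fix: List[Tuple[str, str, int]] = []
    if net_proton:
        fix.append(("products" if net_proton > 0 else "substrates", "proton", abs(net_proton)))
    if net_water:
        fix.append(("products" if net_water > 0 else "substrates", "water", abs(net_water)))
    return fix or None


def propose_balance_fix(
    model: MetabolicModel, finding: BalanceFinding
) -> Optional[Reaction]:
    """Amended copy of the reaction with the proton/water repair applied, or None."""
    if finding.status != "imbalanced":
        raise ValueError(f"finding for {finding.reaction_id} is {finding.status}, not imbalanced")
    fix = finding.proposed_fix or _solve_proton_water_fix(model, finding)
    if fix is None:
        return None
    rxn = model.reactions[finding.reaction_id].copy()
    comp = next((model.metabolites[m].compartment for m in rxn.stoichiometry), "c")
    species = {
        "proton": _find_species(model, ("H",), comp),
        "water": _find_species(model, ("H2O",), comp),
    }
    for side, name, count in fix:
        met = species[name]
        if met is None:
            # the repair species is not in the model: synthesise it
            met = Metabolite(
                id={"proton": f"h_{comp}", "water": f"h2o_{comp}"}[name],
                name=name,
                formula={"proton": "H", "water": "H2O"}[name],
                charge={"proton": 1, "water": 0}[name],
                compartment=comp,
            )
            model.add_metabolite(met)
        sign = 1.0 if side == "products" else -1.0
        rxn.stoichiometry[met.id] = rxn.stoichiometry.get(met.id, 0.0) + sign * count
        if rxn.stoichiometry[met.id] == 0.0:
            del rxn.stoichiometry[met.id]
    return rxn


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------

def _stoich_key(stoich: Dict[str, float]) -> Tuple:
    return tuple(sorted((m, round(c, 12)) for m, c in stoich.items()))


def find_duplicates(model: MetabolicModel) -> List[List[str]]:
    """Groups of reactions with identical stoichiometry (exact coefficients),
    or exactly sign-flipped stoichiometry with mirrored bounds (antiparallel).

    GPRs may differ between group members; they are reported, not merged.
    """
    canonical: Dict[Tuple, List[str]] = {}
    for rxn in model.reactions.values():
        fwd = _stoich_key(rxn.stoichiometry)
        rev = _stoich_key({m: -c for m, c in rxn.stoichiometry.items()})
        key = min(fwd, rev)
        canonical.setdefault(key, []).append(rxn.id)

    groups: List[List[str]] = []
    for bucket in canonical.values():
        if len(bucket) < 2:
            continue
        # within a bucket, verify pairwise duplicate semantics via union-find
        parent = {rid: rid for rid in bucket}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(bucket):
            for b in bucket[i + 1:]:
                ra, rb = model.reactions[a], model.reactions[b]
                same = _stoich_key(ra.stoichiometry) == _stoich_key(rb.stoichiometry)
                if same:
                    dup = True
                else:  # antiparallel: bounds must mirror
                    dup = (
                        abs(ra.lower_bound + rb.upper_bound) < 1e-9
                        and abs(ra.upper_bound + rb.lower_bound) < 1e-9
                    )
                if dup:
                    parent[find(a)] = find(b)
        clusters: Dict[str, List[str]] = {}
        for rid in bucket:
            clusters.setdefault(find(rid), []).append(rid)
        groups.extend(sorted(c) for c in clusters.values() if len(c) > 1)
    return sorted(groups)


# ---------------------------------------------------------------------------
# connectivity: orphans, dead ends, blocked reactions, exchange proposals
# ---------------------------------------------------------------------------

def find_dead_ends(model: MetabolicModel) -> Tuple[List[str], List[str]]:
    """(dead_end_ids, orphan_ids).

    An orphan appears in no reaction. A dead end can only ever be produced
    or only ever consumed, taking declared reversibility (bounds) into
    account; an exchange reaction counts as producer (uptake open) and/or
    consumer (secretion open) of its metabolite.
    """
    producible = {mid: False for mid in model.metabolites}
    consumable = {mid: False for mid in model.metabolites}
    referenced = {mid: False for mid in model.metabolites}
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for mid, coeff in rxn.stoichiometry.items():
            referenced[mid] = True
            if (coeff > 0 and fwd) or (coeff < 0 and rev):
                producible[mid] = True
            if (coeff < 0 and fwd) or (coeff > 0 and rev):
                consumable[mid] = True
    orphans = [mid for mid, ref in referenced.items() if not ref]
    dead_ends = [
        mid
        for mid in model.metabolites
        if referenced[mid] and not (producible[mid] and consumable[mid])
    ]
    return dead_ends, orphans


def find_blocked(model: MetabolicModel, medium: Optional[Medium] = None) -> List[str]:
    """Reactions whose flux range is {0} under an open objective (FVA at fraction 0)."""
    work = apply_medium(model, medium) if medium is not None else model
    feas = solve_fba(work, objective={next(iter(work.reactions)): 0.0}, sense="max") \
        if not work.objective else solve_fba(work)
    if feas.status == "infeasible":
        raise InfeasibleMediumError("model is infeasible under the given medium")
    ranges = flux_variability(work, objective_fraction=0.0)
    return [rid for rid, (lo, hi) in ranges.items() if abs(lo) < BLOCKED_TOL and abs(hi) < BLOCKED_TOL]


def propose_exchanges(model: MetabolicModel) -> List[Reaction]:
    """Secretion-only boundary reactions for accumulating (dead-end) metabolites.

    Extracellular dead ends get ``EX_<id>``, intracellular ones a demand
    reaction ``DM_<id>``; metabolites that already have an exchange are
    skipped.
    """
    dead_ends, _ = find_dead_ends(model)
    have_exchange = {
        next(iter(r.stoichiometry)) for r in model.exchanges()
    }
    proposals = []
    for mid in dead_ends:
        if mid in have_exchange:
            continue
        met = model.metabolites[mid]
        prefix = "EX_" if met.compartment == "e" else "DM_"
        rid = prefix + mid
        if rid in model.reactions:
            continue
        proposals.append(
            Reaction(
                id=rid,
                name=f"{'exchange' if prefix == 'EX_' else 'demand'} for {mid}",
                stoichiometry={mid: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                kind="exchange",
            )
        )
    return proposals


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

def read_dg_table(path) -> Dict[str, float]:
    """TSV with columns ``reaction_id`` and ``dG_prime_kJ_per_mol``."""
    out = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["reaction_id"]] = float(row["dG_prime_kJ_per_mol"])
    return out


def assign_directionality(
    model: MetabolicModel,
    dg_table: Dict[str, float],
    rule: DirectionalityRule = DirectionalityRule(),
    apply: bool = True,
) -> Dict[str, str]:
    """Thermodynamic direction per reaction, from standard transformed dG°'.

    Strongly exergonic (< -threshold) reactions become forward-only,
    strongly endergonic (> +threshold) become reverse-only, anything within
    the band stays reversible (inequalities strict at the threshold);
    reactions absent from the table are ``unassigned``. With ``apply`` the
    constraining assignments tighten the bounds in place (bounds are only
    ever closed, never opened).
    """
    assignments: Dict[str, str] = {}
    for rid, rxn in model.reactions.items():
        if rid not in dg_table:
            assignments[rid] = "unassigned"
            continue
        dg = dg_table[rid]
        if dg < -rule.threshold_kj_per_mol:
            assignments[rid] = "forward_only"
            if apply and rxn.lower_bound < 0:
                rxn.lower_bound = 0.0
        elif dg > rule.threshold_kj_per_mol:
            assignments[rid] = "reverse_only"
            if apply and rxn.upper_bound > 0:
                rxn.upper_bound = 0.0
        else:
            assignments[rid] = "reversible"
    return assignments


def directionality_conflicts(
    model: MetabolicModel, dg_table: Dict[str, float], rule: DirectionalityRule = DirectionalityRule()
) -> List[str]:
    """Reactions whose current bounds contradict their thermodynamic direction."""
    assignments = assign_directionality(model, dg_table, rule, apply=False)
    conflicts = []
    for rid, assignment in assignments.items():
        rxn = model.reactions[rid]
        if assignment == "forward_only" and rxn.upper_bound <= 0 and rxn.lower_bound < 0:
            conflicts.append(rid)  # can only run backwards
        elif assignment == "reverse_only" and rxn.lower_bound >= 0 and rxn.upper_bound > 0:
            conflicts.append(rid)
    return conflicts


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    balance: List[BalanceFinding] = field(default_factory=list)
    duplicate_groups: List[List[str]] = field(default_factory=list)
    dead_ends: List[str] = field(default_factory=list)
    orphans: List[str] = field(default_factory=list)
    blocked: Optional[List[str]] = None
    directionality: Dict[str, str] = field(default_factory=dict)
    directionality_conflicts: List[str] = field(default_factory=list)

    @property
    def imbalanced(self) -> List[BalanceFinding]:
        return [f for f in self.balance if f.status == "imbalanced"]

    @property
    def indeterminate(self) -> List[BalanceFinding]:
        return [f for f in self.balance if f.status == "indeterminate"]

    def is_clean(self) -> bool:
        """No curation defects: balance, duplicates, dead ends, orphans,
        directionality conflicts. Blocked reactions are reported separately
        (a blocked boundary reaction may be an intended negative control)."""
        return not (
            self.imbalanced
            or self.duplicate_groups
            or self.dead_ends
            or self.orphans
            or self.directionality_conflicts
        )

    def to_json(self, path=None) -> str:
        doc = {
            "imbalanced": [
                {
                    "reaction_id": f.reaction_id,
                    "element_imbalance": f.element_imbalance,
                    "charge_imbalance": f.charge_imbalance,
                    "proposed_fix": f.proposed_fix,
                }
                for f in self.imbalanced
            ],
            "indeterminate": [f.reaction_id for f in self.indeterminate],
            "duplicate_groups": self.duplicate_groups,
            "dead_ends": self.dead_ends,
            "orphans": self.orphans,
            "blocked": self.blocked,
            "directionality": self.directionality,
            "directionality_conflicts": self.directionality_conflicts,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["category", "entity", "detail"])
            for f in self.imbalanced:
                w.writerow(
                    [
                        "imbalanced",
                        f.reaction_id,
                        "; ".join(f"{el}:{v:+g}" for el, v in sorted(f.element_imbalance.items()))
                        + (f"; charge:{f.charge_imbalance:+g}" if f.charge_imbalance else ""),
                    ]
                )
            for f in self.indeterminate:
                w.writerow(["indeterminate", f.reaction_id, "missing formula or charge"])
            for i, grp in enumerate(self.duplicate_groups):
                w.writerow(["duplicate_group", f"group{i}", ",".join(grp)])
            for mid in self.dead_ends:
                w.writerow(["dead_end", mid, ""])
            for mid in self.orphans:
                w.writerow(["orphan", mid, ""])
            for rid in self.blocked or []:
                w.writerow(["blocked", rid, ""])
            for rid in self.directionality_conflicts:
                w.writerow(["direction_conflict", rid, self.directionality.get(rid, "")])


def run_qc(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    dg_table: Optional[Dict[str, float]] = None,
    rule: DirectionalityRule = DirectionalityRule(),
    with_blocked: bool = False,
) -> QCReport:
    """Run the full curation audit; blocked-reaction census only on request
    (it requires a feasible medium and one LP pair per reaction)."""
    dead_ends, orphans = find_dead_ends(model)
    report = QCReport(
        balance=check_balance(model),
        duplicate_groups=find_duplicates(model),
        dead_ends=dead_ends,
        orphans=orphans,
    )
    if dg_table:
        report.directionality = assign_directionality(model, dg_table, rule, apply=False)
        report.directionality_conflicts = directionality_conflicts(model, dg_table, rule)
    if with_blocked:
        report.blocked = find_blocked(model, medium)
    return report
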