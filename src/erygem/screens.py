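"""Growth-phenotype screens and single-gene deletion analysis.

A substrate supports growth in silico when the FBA optimum of the biomass
reaction exceeds 1e-5 1/h with that substrate as the sole source of its
class (carbon or nitrogen). The same threshold classifies genes as
essential or dispensable after constraining to zero every reaction whose
GPR rule evaluates false under the knockout.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .fba import Medium, apply_medium, solve_fba, _is_organic
from .model import MetabolicModel, parse_formula

log = logging.getLogger(__name__)

#: growth call threshold (1/h): below this the simulated optimum is "no growth"
GROWTH_THRESHOLD = 1e-5

#: default uptake bound for the screened source (mmol/gDCW/h)
DEFAULT_SOURCE_UPTAKE = 10.0


@dataclass
class GrowthCall:
    source_id: str
    predicted: Optional[str]  # growth | no_growth | None (untestable)
    mu_sim: Optional[float]
    observed: Optional[str] = None  # growth | no_growth
    source_name: str = ""

    @property
    def agrees(self) -> Optional[bool]:
        if self.predicted is None or self.observed is None:
            return None
        return self.predicted == self.observed


@dataclass
class GeneDeletionResult:
    gene_id: str
    growth_rate: float
    wild_type_growth: float
    classification: str  # essential | dispensable
    disabled_reactions: List[str]


def _contains_nitrogen(model: MetabolicModel, met_id: str) -> bool:
    met = model.metabolites[met_id]
    if not met.formula:
        return False
    try:
        return parse_formula(met.formula).get("N", 0) > 0
    except ValueError:
        return False


def _close_competing_uptakes(model: MetabolicModel, role: str, keep: str):
    """Shut the uptake of every same-role source except *keep*.

    Carbon screens close organic-carbon uptakes (CO2 and friends stay
    free); nitrogen screens close every nitrogen-containing uptake
    including ammonia. The complementary nutrient class is left open.
    """
    for rxn in model.exchanges():
        if rxn.id == keep:
            continue
        (mid,) = rxn.stoichiometry
        if role == "carbon" and _is_organic(model, mid):
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        elif role == "nitrogen" and _contains_nitrogen(model, mid):
            rxn.lower_bound = max(rxn.lower_bound, 0.0)


def screen_sources(
    model: MetabolicModel,
    sources: Sequence[str],
    role: str = "carbon",
    base_medium: Optional[Medium] = None,
    uptake: float = DEFAULT_SOURCE_UPTAKE,
    observations: Optional[Dict[str, str]] = None,
) -> List[GrowthCall]:
    """Growth call per source exchange, each tested as the sole source of its role."""
    if role not in ("carbon", "nitrogen"):
        raise ValueError("role must be 'carbon' or 'nitrogen'")
    base = apply_medium(model, base_medium) if base_medium is not None else model
    biomass = base.biomass_reaction_id()
    if biomass is None:
        raise ValueError("model declares no biomass reaction or objective")
    calls = []
    for source in sources:
        if source not in base.reactions or base.reactions[source].kind != "exchange":
            log.warning("screen: %s has no exchange reaction, recorded as untestable", source)
            calls.append(GrowthCall(source_id=source, predicted=None, mu_sim=None,
                                    observed=(observations or {}).get(source)))
            continue
        work = base.copy()
        _close_competing_uptakes(work, role, keep=source)
        rxn = work.reactions[source]
        rxn.lower_bound = -abs(uptake)
        sol = solve_fba(work, objective={biomass: 1.0}, sense="max")
        mu = sol.objective_value if sol.optimal else 0.0
        calls.append(
            GrowthCall(
                source_id=source,
                predicted="growth" if mu > GROWTH_THRESHOLD else "no_growth",
                mu_sim=mu,
                observed=(observations or {}).get(source),
            )
        )
    return calls


def screen_accuracy(calls: Iterable[GrowthCall]) -> float:
    """Percent agreement between predictions and observations, 1 decimal."""
    scored = [c for c in calls if c.agrees is not None]
    if not scored:
        raise ValueError("no growth calls carry observations")
    agree = sum(1 for c in scored if c.agrees)
    return round(100.0 * agree / len(scored), 1)


def load_observations(path) -> List[Tuple[str, str, str]]:
    """Phenotype table rows: (source_name, exchange_id, 'growth'/'no_growth')."""
    rows = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            obs = row["observed"].strip()
            rows.append(
                (
                    row["source_name"],
                    row["exchange_id"],
                    "growth" if obs == "+" else "no_growth",
                )
            )
    return rows


def write_growth_calls(calls: Sequence[GrowthCall], path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["source_id", "predicted", "observed", "mu_sim"])
        for c in calls:
            w.writerow([c.source_id, c.predicted or "untestable", c.observed or "",
                        "" if c.mu_sim is None else f"{c.mu_sim:.6g}"])


# ---------------------------------------------------------------------------
# single-gene deletion
# ---------------------------------------------------------------------------

def single_gene_deletion(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    genes: Optional[Sequence[str]] = None,
    threshold: float = GROWTH_THRESHOLD,
) -> List[GeneDeletionResult]:
    """Knock out each gene in turn and classify it by the re-solved optimum.

    A knockout constrains to (0, 0) exactly those reactions whose GPR
    evaluates false without the gene; all other bounds stay untouched. A
    gene is essential when the knockout optimum falls below *threshold*.
    Raises if the wild type itself cannot grow on the medium.
    """
    work = apply_medium(model, medium) if medium is not None else model.copy()
    biomass = work.biomass_reaction_id()
    if biomass is None:
        raise ValueError("model declares no biomass reaction or objective")
    wild = solve_fba(work, objective={biomass: 1.0}, sense="max")
    if not wild.optimal or wild.objective_value <= threshold:
        raise RuntimeError(
            f"wild type does not grow on the given medium (status {wild.status}, "
            f"mu {wild.objective_value})"
        )
    wt_mu = wild.objective_value

    results = []
    for gid in genes if genes is not None else list(work.genes):
        disabled = [
            rxn.id
            for rxn in work.reactions.values()
            if not rxn.gpr.is_empty and gid in rxn.gpr.genes() and not rxn.gpr.evaluate({gid})
        ]
        if not disabled:
            results.append(
                GeneDeletionResult(gid, wt_mu, wt_mu, "dispensable", [])
            )
            continue
        saved = {rid: (work.reactions[rid].lower_bound, work.reactions[rid].upper_bound)
                 for rid in disabled}
        for rid in disabled:
            work.reactions[rid].lower_bound = 0.0
            work.reactions[rid].upper_bound = 0.0
        sol = solve_fba(work, objective={biomass: 1.0}, sense="max")
        mu = sol.objective_value if sol.optimal else 0.0
        for rid, (lb, ub) in saved.items():
            work.reactions[rid].lower_bound = lb
            work.reactions[rid].upper_bound = ub
        results.append(
            GeneDeletionResult(
                gene_id=gid,
                growth_rate=mu,
                wild_type_growth=wt_mu,
                classification="essential" if mu < threshold else "dispensable",
                disabled_reactions=disabled,
            )
        )
    return results


def write_deletion_results(results: Sequence[GeneDeletionResult], path):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "growth_rate", "wild_type_growth", "classification",
                    "disabled_reactions"])
        for r in results:
            w.writerow([r.gene_id, f"{r.growth_rate:.6g}", f"{r.wild_type_growth:.6g}",
                        r.classification, ",".join(r.disabled_reactions)])


# ---------------------------------------------------------------------------
# erythromycin rate at fixed growth
# ---------------------------------------------------------------------------

def qery_at_fixed_growth(
    model: MetabolicModel,
    mu_target: float,
    q_o2: Optional[float] = None,
    q_co2: Optional[float] = None,
    ery_exchange: str = "EX_ery_e",
    o2_exchange: str = "EX_o2_e",
    co2_exchange: str = "EX_co2_e",
    biomass_id: Optional[str] = None,
    gas_tolerance: float = 0.05,
):
    """Maximum specific erythromycin rate at an experimentally fixed growth rate.

    The biomass flux is pinned to ``mu_target``; measured O2 uptake and CO2
    evolution rates, when given, are held within a +/-5% band; the
    objective switches to the erythromycin exchange. Infeasibility names
    the binding constraint.
    """
    work = model.copy()
    biomass = biomass_id or work.biomass_reaction_id()
    if biomass is None:
        raise ValueError("model declares no biomass reaction or objective")
    work.reactions[biomass].lower_bound = mu_target
    work.reactions[biomass].upper_bound = mu_target
    constrained = {biomass: "biomass"}
    if q_o2 is not None:
        rxn = work.reactions[o2_exchange]
        rxn.lower_bound = -abs(q_o2) * (1 + gas_tolerance)
        rxn.upper_bound = -abs(q_o2) * (1 - gas_tolerance)
        constrained[o2_exchange] = "O2 uptake"
    if q_co2 is not None:
        rxn = work.reactions[co2_exchange]
        rxn.lower_bound = abs(q_co2) * (1 - gas_tolerance)
        rxn.upper_bound = abs(q_co2) * (1 + gas_tolerance)
        constrained[co2_exchange] = "CO2 evolution"
    sol = solve_fba(work, objective={ery_exchange: 1.0}, sense="max")
    if not sol.optimal:
        culprits = []
        for rid, label in constrained.items():
            probe = work.copy()
            probe.reactions[rid].lower_bound = model.reactions[rid].lower_bound
            probe.reactions[rid].upper_bound = model.reactions[rid].upper_bound
            if solve_fba(probe, objective={ery_exchange: 1.0}).optimal:
                culprits.append(label)
        sol.message = (
            f"infeasible at mu = {mu_target}"
            + (f"; binding constraint(s): {', '.join(culprits)}" if culprits else "")
        )
    return sol
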