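"""Flux balance analysis on top of scipy's HiGHS linear-programming solver.

The steady-state problem is

    maximise  c'v   subject to   S v = 0,   lb <= v <= ub

where columns of S are reactions and v is the flux vector (mmol/gDCW/h).
Besides the primal solution the solver's dual values are exposed:
per-metabolite shadow prices (sensitivity of the optimum to the
mass-balance right-hand side) and per-reaction bound sensitivities
(marginal objective gain per unit relaxation of an active bound).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix, formula_carbon_count

log = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-8
MASS_BALANCE_TOL = 1e-6


class InfeasibleMediumError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    """Result of one LP solve.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``.
    ``shadow_prices`` maps metabolite id to the dual of its mass-balance
    row on the *maximisation* scale: d(optimum)/d(b_i). ``bound_sensitivities``
    maps reaction id to the marginal objective change per unit relaxation of
    whichever of its bounds is active (0 when neither binds).
    """

    status: str
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: Optional[float] = None
    shadow_prices: Dict[str, float] = field(default_factory=dict)
    bound_sensitivities: Dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]

    def to_tsv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["reaction_id", "flux"])
            for rid, v in self.fluxes.items():
                w.writerow([rid, f"{v:.10g}"])


@dataclass
class Medium:
    """Exchange-bound overrides; uptake is a negative flux.

    With ``sole_carbon`` set, every other exchange of an organic
    (carbon-containing, CO2/bicarbonate excepted) metabolite has its uptake
    closed, mirroring the single-carbon-source convention of growth
    simulations; inorganic species stay freely transportable.
    """

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    sole_carbon: bool = False

    @classmethod
    def from_tsv(cls, path) -> "Medium":
        sole = False
        bounds: Dict[str, Tuple[float, float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "sole_carbon" in line:
                        sole = line.split(":", 1)[1].strip().lower() in ("true", "1", "yes")
                    continue
                parts = line.split("\t")
                if parts[0] == "exchange_id":
                    continue
                bounds[parts[0]] = (float(parts[1]), float(parts[2]))
        return cls(bounds=bounds, sole_carbon=sole)

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# sole_carbon: {str(self.sole_carbon).lower()}\n")
            fh.write("exchange_id\tlb\tub\n")
            for rid, (lb, ub) in self.bounds.items():
                fh.write(f"{rid}\t{lb:g}\t{ub:g}\n")


#: formulas treated as inorganic even though some contain carbon
INORGANIC_FORMULAS = {
    "H2O", "O2", "CO2", "H", "H3N", "H4N", "NH3", "NH4",
    "HO4P", "H3O4P", "O4P", "O4S", "H2O4S", "HCO3", "CO3", "NO3", "H3PO4",
}


def _is_organic(model: MetabolicModel, met_id: str) -> bool:
    met = model.metabolites[met_id]
    if not met.formula or met.formula in INORGANIC_FORMULAS:
        return False
    n_c = formula_carbon_count(met.formula)
    return bool(n_c)


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of *model* with the medium's exchange bounds applied."""
    out = model.copy()
    for rid, (lb, ub) in medium.bounds.items():
        rxn = out.reactions.get(rid)
        if rxn is None:
            raise KeyError(f"medium names unknown reaction {rid!r}")
        if rxn.kind != "exchange":
            raise ValueError(f"medium names non-exchange reaction {rid!r}")
        rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)
    if medium.sole_carbon:
        for rxn in out.exchanges():
            if rxn.id in medium.bounds:
                continue
            (mid,) = rxn.stoichiometry
            if _is_organic(out, mid):
                rxn.lower_bound = max(rxn.lower_bound, 0.0)  # close uptake only
    return out


def _solve_lp(
    S: sparse.csr_matrix,
    c: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    sense: str,
    extra_A: Optional[np.ndarray] = None,
    extra_lb: Optional[np.ndarray] = None,
    extra_ub: Optional[np.ndarray] = None,
):
    """minimise/maximise c'v s.t. S v = 0, optional extra row constraints, bounds."""
    sign = -1.0 if sense == "max" else 1.0
    kwargs = dict(
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": OPTIMALITY_TOL},
    )
    if extra_A is not None:
        A = sparse.csr_matrix(np.atleast_2d(extra_A))
        rows, rhs = [], []
        for i, (lo, hi) in enumerate(zip(np.asarray(extra_lb), np.asarray(extra_ub))):
            if np.isfinite(hi):
                rows.append(A[i])
                rhs.append(hi)
            if np.isfinite(lo):
                rows.append(-A[i])
                rhs.append(-lo)
        if rows:
            kwargs["A_ub"] = sparse.vstack(rows).tocsr()
            kwargs["b_ub"] = np.asarray(rhs, dtype=float)
    res = linprog(sign * c, **kwargs)
    return res, sign


def solve_fba(
    model: MetabolicModel,
    objective: Optional[Dict[str, float]] = None,
    sense: str = "max",
) -> FluxSolution:
    """Solve the FBA linear programme for *model*.

    Infeasibility/unboundedness is reported in ``status``, never raised.
    """
    objective = objective if objective is not None else model.objective
    if not objective:
        raise ValueError("no objective given and model declares none")
    S, met_index, rxn_index = build_stoichiometric_matrix(model)
    n = S.shape[1]
    c = np.zeros(n)
    for rid, w in objective.items():
        c[rxn_index[rid]] = w
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])

    res, sign = _solve_lp(S, c, lb, ub, sense)
    if res.status == 2:
        return FluxSolution(status="infeasible", message=res.message)
    if res.status == 3:
        return FluxSolution(status="unbounded", message=res.message)
    if not res.success:
        return FluxSolution(status="infeasible", message=res.message)

    fluxes = {rid: float(res.x[j]) for rid, j in rxn_index.items()}
    z = float(sign * res.fun)
    # linprog marginals are on the minimisation scale: flip for maximisation
    duals = {mid: float(sign * res.eqlin.marginals[i]) for mid, i in met_index.items()}
    # d z*/d(bound value) on the maximisation scale; at most one bound is
    # active per reaction so the two marginals never overlap.
    sens = {
        rid: float(sign * (res.lower.marginals[j] + res.upper.marginals[j]))
        for rid, j in rxn_index.items()
    }
    return FluxSolution(
        status="optimal",
        fluxes=fluxes,
        objective_value=z,
        shadow_prices=duals,
        bound_sensitivities=sens,
        message=res.message,
    )


def verify_solution(model: MetabolicModel, sol: FluxSolution) -> Dict[str, float]:
    """Residuals of an optimal solution: mass balance, bound violation, duality gap."""
    S, met_index, rxn_index = build_stoichiometric_matrix(model)
    v = np.array([sol.fluxes[rid] for rid in rxn_index])
    resid = S @ v
    scale = max(1.0, float(np.max(np.abs(v))) if v.size else 1.0)
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    bound_viol = float(np.max(np.maximum(lb - v, v - ub), initial=0.0))
    # dual objective for max c'v s.t. Sv=0, l<=v<=u (y free, shadow prices):
    #   z = sum_j mu_j with mu_j the bound sensitivity times the active bound.
    # Reconstruct from duals: z_dual = sum_i y_i*0 + l'lam_l + u'lam_u; here we
    # recover lam from c - S'y since linprog does not expose both multipliers.
    y = np.array([sol.shadow_prices[mid] for mid in met_index])
    c = np.zeros(len(rxn_index))
    for rid, w in (model.objective or {}).items():
        if rid in rxn_index:
            c[rxn_index[rid]] = w
    lam = c - S.T @ y  # reduced costs on the maximisation scale
    z_dual = float(np.sum(np.where(lam > 0, lam * ub, lam * lb)))
    return {
        "mass_balance_inf_norm": float(np.max(np.abs(resid), initial=0.0)),
        "mass_balance_rel": float(np.max(np.abs(resid), initial=0.0)) / scale,
        "bound_violation": bound_viol,
        "duality_gap_rel": abs(z_dual - (sol.objective_value or 0.0))
        / max(1.0, abs(sol.objective_value or 0.0)),
    }


def flux_variability(
    model: MetabolicModel,
    objective_fraction: float = 0.0,
    objective: Optional[Dict[str, float]] = None,
    reactions: Optional[Iterable[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux (min, max) with the objective locked to a fraction of z*.

    With ``objective_fraction`` 0 the objective is unconstrained, which is
    the blocked-reaction census setting.
    """
    objective = objective if objective is not None else model.objective
    S, met_index, rxn_index = build_stoichiometric_matrix(model)
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    c = np.zeros(n)
    for rid, w in (objective or {}).items():
        c[rxn_index[rid]] = w

    extra_A = extra_lb = extra_ub = None
    if objective_fraction > 0.0:
        base = solve_fba(model, objective=objective, sense="max")
        if not base.optimal:
            raise InfeasibleMediumError(f"base FBA is {base.status}: {base.message}")
        z_star = base.objective_value
        extra_A = c.reshape(1, -1)
        lock = objective_fraction * z_star
        extra_lb = np.array([lock if z_star >= 0 else z_star / objective_fraction])
        extra_ub = np.array([np.inf])

    targets = list(reactions) if reactions is not None else list(rxn_index)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        j = rxn_index[rid]
        obj = np.zeros(n)
        obj[j] = 1.0
        lo_res, _ = _solve_lp(S, obj, lb, ub, "min", extra_A, extra_lb, extra_ub)
        hi_res, _ = _solve_lp(S, obj, lb, ub, "max", extra_A, extra_lb, extra_ub)
        if not (lo_res.success and hi_res.success):
            raise InfeasibleMediumError(f"FVA subproblem for {rid} failed")
        out[rid] = (float(lo_res.fun), float(-hi_res.fun))
    return out


def parsimonious_flux(
    model: MetabolicModel,
    objective: Optional[Dict[str, float]] = None,
) -> FluxSolution:
    """pFBA: among optima of the FBA problem, minimise total absolute flux.

    The flux vector is split into forward/reverse parts and a second LP
    minimises their sum at the optimal objective, giving a deterministic,
    thermodynamically leaner flux map than an arbitrary optimal vertex.
    """
    objective = objective if objective is not None else model.objective
    base = solve_fba(model, objective=objective, sense="max")
    if not base.optimal:
        return base
    z_star = base.objective_value

    S, met_index, rxn_index = build_stoichiometric_matrix(model)
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    c = np.zeros(n)
    for rid, w in objective.items():
        c[rxn_index[rid]] = w

    # variables [p; q], v = p - q, p,q >= 0
    S2 = sparse.hstack([S, -S]).tocsr()
    obj_row = sparse.hstack(
        [sparse.csr_matrix(c.reshape(1, -1)), sparse.csr_matrix(-c.reshape(1, -1))]
    ).tocsr()
    cost = np.ones(2 * n)
    p_lb, p_ub = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    q_lb, q_ub = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    bounds = np.column_stack(
        [np.concatenate([p_lb, q_lb]), np.concatenate([p_ub, q_ub])]
    )
    tol = max(1e-9, abs(z_star) * 1e-9)
    res = linprog(
        cost,
        A_eq=sparse.vstack([S2, obj_row]).tocsr(),
        b_eq=np.concatenate([np.zeros(S.shape[0]), [z_star]]),
        A_ub=None,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    if not res.success:  # z* at machine tolerance can be marginally infeasible
        res = linprog(
            cost,
            A_eq=S2,
            b_eq=np.zeros(S.shape[0]),
            A_ub=-obj_row,
            b_ub=np.array([-(z_star - tol)]),
            bounds=bounds,
            method="highs",
            options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
        )
    if not res.success:
        return FluxSolution(status="infeasible", message="pFBA stage failed: " + res.message)
    v = res.x[:n] - res.x[n:]
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    z = float(sum(objective.get(rid, 0.0) * fluxes[rid] for rid in objective))
    return FluxSolution(
        status="optimal",
        fluxes=fluxes,
        objective_value=z,
        shadow_prices=base.shadow_prices,
        bound_sensitivities=base.bound_sensitivities,
        message="parsimonious",
    )


def total_absolute_flux(sol: FluxSolution) -> float:
    return float(sum(abs(v) for v in sol.fluxes.values()))
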