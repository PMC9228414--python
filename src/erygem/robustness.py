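"""Robustness analysis of erythromycin synthesis against precursor uptake.

The n-propanol uptake rate is swept over a grid; at each point the uptake
flux is *fixed* (supplementation semantics: what is fed must be taken up)
and the erythromycin exchange is maximised. LP parametric theory makes
the optimum a concave piecewise-linear function of the uptake rate, so
its derivative — the shadow price of propanol, d qEry / d uptake — is
non-increasing: a rise regime (precursor-limited), a plateau (some other
resource limits) and possibly a decline (forced uptake displaces better
substrate use).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .fba import Medium, apply_medium, solve_fba
from .model import MetabolicModel

log = logging.getLogger(__name__)

#: default sweep grid: 0 to 0.2 mmol/gDCW/h in steps of 0.005
DEFAULT_GRID = [round(0.005 * i, 10) for i in range(41)]

PLATEAU_EPS = 1e-6


@dataclass
class RobustnessCurve:
    exchange_id: str
    uptakes: List[float]
    qery: List[Optional[float]]  # None where the fixed uptake is infeasible
    shadow_prices: List[Optional[float]]
    objective_id: str = "EX_ery_e"
    breakpoints: List[float] = field(default_factory=list)

    def feasible_points(self) -> List[Tuple[float, float]]:
        return [(u, q) for u, q in zip(self.uptakes, self.qery) if q is not None]

    def to_tsv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["uptake", "qEry", "shadow_price"])
            for u, q, s in zip(self.uptakes, self.qery, self.shadow_prices):
                w.writerow(
                    [f"{u:.6g}",
                     "infeasible" if q is None else f"{q:.10g}",
                     "" if s is None else f"{s:.10g}"]
                )

    def plot(self, path):  # pragma: no cover - optional plotting
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax1 = plt.subplots(figsize=(6, 4))
        pts = self.feasible_points()
        ax1.plot([p[0] for p in pts], [p[1] for p in pts], "o-", color="tab:blue")
        ax1.set_xlabel("n-propanol uptake (mmol/gDCW/h)")
        ax1.set_ylabel("qEry (mmol/gDCW/h)", color="tab:blue")
        ax2 = ax1.twinx()
        sp = [(u, s) for u, s in zip(self.uptakes, self.shadow_prices) if s is not None]
        ax2.plot([p[0] for p in sp], [p[1] for p in sp], "s--", color="tab:red")
        ax2.set_ylabel("shadow price (mmol/mmol)", color="tab:red")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _fix_uptake(model: MetabolicModel, exchange_id: str, rate: float) -> MetabolicModel:
    work = model.copy()
    rxn = work.reactions.get(exchange_id)
    if rxn is None:
        raise KeyError(f"no exchange reaction {exchange_id!r} in the model")
    rxn.lower_bound = -rate
    rxn.upper_bound = -rate
    return work


def uptake_sweep(
    model: MetabolicModel,
    exchange_id: str,
    grid: Sequence[float] = DEFAULT_GRID,
    objective: Optional[Dict[str, float]] = None,
    base_medium: Optional[Medium] = None,
) -> RobustnessCurve:
    """Optimal qEry and its shadow price at each fixed uptake rate of the grid."""
    if any(b <= a for a, b in zip(grid, grid[1:])) or any(r < 0 for r in grid):
        raise ValueError("grid must be nonnegative and strictly increasing")
    base = apply_medium(model, base_medium) if base_medium is not None else model
    if exchange_id not in base.reactions:
        raise KeyError(f"no exchange reaction {exchange_id!r} in the model")
    objective = objective or {"EX_ery_e": 1.0}
    obj_id = next(iter(objective))

    qery: List[Optional[float]] = []
    shadows: List[Optional[float]] = []
    for rate in grid:
        sol = solve_fba(_fix_uptake(base, exchange_id, rate), objective=objective)
        if not sol.optimal:
            qery.append(None)
            shadows.append(None)
            continue
        qery.append(sol.objective_value)
        # dual of the fixed-uptake constraint: d z / d(bound value) with the
        # bound value = -rate, so d z / d rate flips the sign.
        shadows.append(-sol.bound_sensitivities.get(exchange_id, 0.0))

    curve = RobustnessCurve(
        exchange_id=exchange_id, uptakes=list(grid), qery=qery,
        shadow_prices=shadows, objective_id=obj_id,
    )
    curve.breakpoints = _detect_breakpoints(curve)
    return curve


def _detect_breakpoints(curve: RobustnessCurve, tol: float = 1e-6) -> List[float]:
    """Grid points where the piecewise-linear slope changes."""
    pts = curve.feasible_points()
    if len(pts) < 3:
        return []
    out = []
    for (u0, q0), (u1, q1), (u2, q2) in zip(pts, pts[1:], pts[2:]):
        s01 = (q1 - q0) / (u1 - u0)
        s12 = (q2 - q1) / (u2 - u1)
        if abs(s12 - s01) > tol:
            out.append(u1)
    return out


def shadow_price_at(
    model: MetabolicModel,
    exchange_id: str,
    rate: float,
    objective: Optional[Dict[str, float]] = None,
    step: float = 1e-3,
    base_medium: Optional[Medium] = None,
) -> float:
    """Marginal qEry gain per unit uptake at *rate*.

    Central finite difference with the given step, cross-checked against
    the LP dual of the fixed-uptake constraint; at a breakpoint (left and
    right slopes disagree) the right derivative is returned.
    """
    base = apply_medium(model, base_medium) if base_medium is not None else model
    objective = objective or {"EX_ery_e": 1.0}

    def z(r: float) -> Optional[float]:
        if r < 0:
            return None
        sol = solve_fba(_fix_uptake(base, exchange_id, r), objective=objective)
        return sol.objective_value if sol.optimal else None

    z0 = z(rate)
    if z0 is None:
        raise ValueError(f"uptake rate {rate} is infeasible for {exchange_id}")
    z_plus, z_minus = z(rate + step), z(rate - step)
    if z_plus is None:
        if z_minus is None:
            raise ValueError(f"cannot differentiate at {rate}: neighbours infeasible")
        return (z0 - z_minus) / step  # only the left slope exists
    right = (z_plus - z0) / step
    if z_minus is None:
        return right
    left = (z0 - z_minus) / step
    if abs(left - right) > 1e-6:
        return right  # breakpoint: report the right derivative
    central = (z_plus - z_minus) / (2 * step)
    dual = -solve_fba(_fix_uptake(base, exchange_id, rate),
                      objective=objective).bound_sensitivities.get(exchange_id, 0.0)
    if abs(central - dual) > 1e-4 * max(1.0, abs(central)):
        log.warning(
            "shadow price at %s=%g: finite difference %g vs LP dual %g",
            exchange_id, rate, central, dual,
        )
    return central


def find_plateau(
    curve: RobustnessCurve, eps: float = PLATEAU_EPS
) -> Tuple[Optional[float], Optional[float]]:
    """(rise_end, decline_start) uptake rates of the robustness curve.

    rise_end is the first grid point whose shadow price drops below +eps,
    decline_start the first below -eps; None when the regime is absent.
    """
    rise_end = decline_start = None
    for u, s in zip(curve.uptakes, curve.shadow_prices):
        if s is None:
            continue
        if rise_end is None and s < eps:
            rise_end = u
        if decline_start is None and s < -eps:
            decline_start = u
            break
    return rise_end, decline_start


def check_concavity(curve: RobustnessCurve, tol: float = 1e-6) -> bool:
    """Every interior point lies on or above the chord of its neighbours."""
    pts = curve.feasible_points()
    for (u0, q0), (u1, q1), (u2, q2) in zip(pts, pts[1:], pts[2:]):
        chord = q0 + (q2 - q0) * (u1 - u0) / (u2 - u0)
        if q1 < chord - tol:
            return False
    return True
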