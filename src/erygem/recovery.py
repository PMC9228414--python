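"""Specific rates, carbon recovery and measured-rate-constrained flux maps.

During a quasi-steady fermentation window the specific rates
(mmol/gDCW/h) of glucose and n-propanol consumption, CO2 evolution,
erythromycin and succinyl-CoA-derived product formation, together with
the specific growth rate mu (1/h), close a carbon balance:

    recovery % = 100 * (qCO2*1 + qEry*37 + qSucCoA*25 + mu*1000/32.75)
                     / (qGlucose*6 + qPropanol*3)

where the integer weights are carbon atoms per molecule (glucose 6,
propanol 3, CO2 1, erythromycin A 37, succinyl-CoA-derived acyl 25) and
1000/32.75 converts growth rate to mmol biomass carbon per gDCW. A
recovery near 100% qualifies the window for flux analysis.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from .fba import FluxSolution, parsimonious_flux
from .model import MetabolicModel

#: molar masses (g/mol) used to convert concentrations to mmol
MOLAR_MASSES = {
    "glucose": 180.16,
    "propanol": 60.10,
    "erythromycin": 733.93,  # erythromycin A
}


@dataclass
class RatePanel:
    """Measured specific rates for one fermentation mode."""

    q_glucose: float  # mmol/gDCW/h, positive = consumed
    q_propanol: float
    q_co2: float  # positive = evolved
    q_ery: float  # positive = produced
    q_succoa: float
    mu: float  # 1/h
    errors: Optional[Dict[str, float]] = None
    mode: str = ""

    def scaled(self, k: float) -> "RatePanel":
        return RatePanel(
            self.q_glucose * k, self.q_propanol * k, self.q_co2 * k,
            self.q_ery * k, self.q_succoa * k, self.mu * k, mode=self.mode,
        )


@dataclass(frozen=True)
class CarbonCoefficients:
    """Carbon atoms per unit flux in the recovery statistic (fixed constants)."""

    glucose: float = 6.0
    propanol: float = 3.0
    co2: float = 1.0
    erythromycin: float = 37.0
    succinyl_coa: float = 25.0
    biomass_factor: float = 1000.0 / 32.75  # mmol C per gDCW per unit mu

    def __post_init__(self):
        for name in ("glucose", "propanol", "co2", "erythromycin", "succinyl_coa", "biomass_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"carbon coefficient {name} must be positive")


def carbon_recovery(panel: RatePanel, coeffs: CarbonCoefficients = CarbonCoefficients()) -> float:
    """Carbon recovery in percent, full precision (see module docstring)."""
    denominator = panel.q_glucose * coeffs.glucose + panel.q_propanol * coeffs.propanol
    if denominator <= 0:
        raise ValueError(
            f"panel {panel.mode or '?'}: no substrate consumption, carbon recovery undefined"
        )
    numerator = (
        panel.q_co2 * coeffs.co2
        + panel.q_ery * coeffs.erythromycin
        + panel.q_succoa * coeffs.succinyl_coa
        + panel.mu * coeffs.biomass_factor
    )
    return 100.0 * numerator / denominator


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round as printed in fermentation tables (half away from zero)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def carbon_recovery_percent(panel: RatePanel, coeffs: CarbonCoefficients = CarbonCoefficients()) -> float:
    """Carbon recovery rounded to one decimal for reporting."""
    return round_half_up(carbon_recovery(panel, coeffs), 1)


# ---------------------------------------------------------------------------
# rate panels from fed-batch time series
# ---------------------------------------------------------------------------

@dataclass
class FermentationSeries:
    """Sampled fed-batch trajectories (12-h cadence by default).

    Concentration units: DCW g/L, glucose g/L, propanol g/L, erythromycin
    ug/mL (= mg/L), cumulative CO2 mmol/L. ``propanol_feed_g_per_l_h`` is
    the continuous feed active from ``feed_start_h`` on; the rate estimator
    needs it to separate consumption from feeding.
    """

    times: List[float]
    dcw: List[float]
    glucose: List[float]
    propanol: List[float]
    erythromycin: List[float]
    co2_cumulative: List[float]
    propanol_feed_g_per_l_h: float = 0.0
    feed_start_h: float = 60.0
    mode: str = ""

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("sample times must be strictly increasing")
        for name in ("dcw", "glucose", "propanol", "erythromycin", "co2_cumulative"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"negative {name} concentration in series")

    def index_of(self, t: float) -> int:
        for i, ti in enumerate(self.times):
            if math.isclose(ti, t):
                return i
        raise ValueError(f"time {t} h is not a sampled point of the series")

    def to_tsv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["time_h", "dcw_g_l", "glucose_g_l", "propanol_g_l",
                        "erythromycin_ug_ml", "co2_cumulative_mmol_l"])
            for i, t in enumerate(self.times):
                w.writerow([t, self.dcw[i], self.glucose[i], self.propanol[i],
                            self.erythromycin[i], self.co2_cumulative[i]])


def rates_from_timeseries(
    series: FermentationSeries,
    window: Tuple[float, float],
    molar_masses: Optional[Dict[str, float]] = None,
) -> RatePanel:
    """Two-point secant specific rates over an analysis window.

    q_X = (delta concentration / delta t) / mean DCW, converted to
    mmol/gDCW/h; mu = (ln X1 - ln X0) / delta t. The propanol secant is
    corrected for the continuous feed active during the window. Window
    endpoints must be sampled times.
    """
    masses = dict(MOLAR_MASSES)
    if molar_masses:
        masses.update(molar_masses)
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    i0, i1 = series.index_of(t0), series.index_of(t1)
    dt = t1 - t0
    x0, x1 = series.dcw[i0], series.dcw[i1]
    if x0 <= 0 or x1 <= 0:
        raise ValueError("nonpositive DCW inside the analysis window")
    x_mean = 0.5 * (x0 + x1)
    mu = (math.log(x1) - math.log(x0)) / dt

    def secant(values: Sequence[float]) -> float:
        return (values[i1] - values[i0]) / dt

    # g/L/h -> mmol/gDCW/h: * 1000 / M / X
    q_glucose = -secant(series.glucose) * 1000.0 / masses["glucose"] / x_mean
    feed_overlap = max(0.0, min(t1, series.times[-1]) - max(t0, series.feed_start_h))
    feed_rate_in_window = series.propanol_feed_g_per_l_h * feed_overlap / dt
    q_propanol = (feed_rate_in_window - secant(series.propanol)) * 1000.0 / masses["propanol"] / x_mean
    # mg/L/h -> mmol/gDCW/h: / M_mg_per_mmol / X
    q_ery = secant(series.erythromycin) / masses["erythromycin"] / x_mean
    q_co2 = secant(series.co2_cumulative) / x_mean
    return RatePanel(
        q_glucose=q_glucose,
        q_propanol=q_propanol,
        q_co2=q_co2,
        q_ery=q_ery,
        q_succoa=0.0,
        mu=mu,
        mode=series.mode,
    )


# ---------------------------------------------------------------------------
# Table-style rate panel I/O
# ---------------------------------------------------------------------------

_PANEL_ROWS = {
    "qGlucose": "q_glucose",
    "qPropanol": "q_propanol",
    "qCO2": "q_co2",
    "qEry": "q_ery",
    "qSucCoA": "q_succoa",
    "mu": "mu",
}


def load_rate_panels(path) -> Dict[str, RatePanel]:
    """Read a rates table (rows = quantities, columns = modes) into panels."""
    with open(path) as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    header = rows[0]
    modes = header[1:]
    values: Dict[str, Dict[str, float]] = {m: {} for m in modes}
    for row in rows[1:]:
        if not row or row[0].startswith("#"):
            continue
        quantity = row[0]
        if quantity not in _PANEL_ROWS:
            continue
        for mode, cell in zip(modes, row[1:]):
            values[mode][_PANEL_ROWS[quantity]] = float(cell)
    out = {}
    for mode in modes:
        v = values[mode]
        missing = set(_PANEL_ROWS.values()) - set(v)
        if missing:
            raise ValueError(f"rates table {path}: mode {mode} missing {sorted(missing)}")
        out[mode] = RatePanel(mode=mode, **v)
    return out


def save_rate_panels(panels: Dict[str, RatePanel], path, with_recovery: bool = True):
    modes = list(panels)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["quantity"] + modes)
        for row_name, attr in _PANEL_ROWS.items():
            w.writerow([row_name] + [f"{getattr(panels[m], attr):.6g}" for m in modes])
        if with_recovery:
            w.writerow(
                ["carbon_recovery_pct"]
                + [f"{carbon_recovery_percent(panels[m]):.1f}" for m in modes]
            )


# ---------------------------------------------------------------------------
# measured-rate-constrained flux mapping
# ---------------------------------------------------------------------------

@dataclass
class ExchangeMapping:
    """Reaction ids linking a rate panel to a model's boundary."""

    glucose: str = "EX_glc__D_e"
    propanol: str = "EX_ppoh_e"
    co2: str = "EX_co2_e"
    erythromycin: str = "EX_ery_e"
    biomass: Optional[str] = None  # default: the model's biomass reaction


def constrained_flux_map(
    model: MetabolicModel,
    panel: RatePanel,
    tolerance: float = 0.05,
    mapping: ExchangeMapping = ExchangeMapping(),
    objective: Optional[Dict[str, float]] = None,
) -> FluxSolution:
    """Flux distribution consistent with a measured rate panel.

    Glucose/propanol uptakes, CO2 and erythromycin secretion and the
    biomass flux are clamped to the measured values within a +/-tolerance
    band; the interior is resolved parsimoniously while maximising
    erythromycin secretion (the reported product). Infeasibility names the
    measured constraint whose removal restores feasibility.
    """
    work = model.copy()
    biomass_id = mapping.biomass or work.biomass_reaction_id()
    if biomass_id is None:
        raise ValueError("model has no biomass reaction and none was named")

    def band(value: float, signed: float) -> Tuple[float, float]:
        lo, hi = signed * value * (1 + tolerance), signed * value * (1 - tolerance)
        return (min(lo, hi), max(lo, hi))

    constraints = {
        mapping.glucose: band(panel.q_glucose, -1.0),
        mapping.propanol: band(panel.q_propanol, -1.0),
        mapping.co2: band(panel.q_co2, +1.0),
        mapping.erythromycin: band(panel.q_ery, +1.0),
        biomass_id: band(panel.mu, +1.0),
    }
    for rid, (lb, ub) in constraints.items():
        rxn = work.reactions.get(rid)
        if rxn is None:
            raise KeyError(f"rate panel maps to unknown reaction {rid!r}")
        rxn.lower_bound, rxn.upper_bound = lb, ub

    objective = objective or {mapping.erythromycin: 1.0}
    sol = parsimonious_flux(work, objective=objective)
    if not sol.optimal:
        culprits = []
        for rid in constraints:
            probe = work.copy()
            original = model.reactions[rid]
            probe.reactions[rid].lower_bound = original.lower_bound
            probe.reactions[rid].upper_bound = original.upper_bound
            if parsimonious_flux(probe, objective=objective).optimal:
                culprits.append(rid)
        sol.message = (
            "measured-rate constraints are infeasible"
            + (f"; relaxing any of {culprits} restores feasibility" if culprits else "")
        )
    return sol


def pathway_sums(model: MetabolicModel, sol: FluxSolution) -> Dict[str, float]:
    """Aggregate |flux| per subsystem (glycolysis, PP pathway, TCA, ...)."""
    out: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        if rxn.subsystem:
            out[rxn.subsystem] = out.get(rxn.subsystem, 0.0) + abs(sol.fluxes.get(rid, 0.0))
    return out
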