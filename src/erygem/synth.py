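"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`make_toy_model` — a lumped, elementally balanced
  erythromycin-producer network (glucose and n-propanol uptake, glycolysis,
  pentose-phosphate NADPH supply, TCA with an explicit succinyl-CoA node,
  propanol -> propionyl-CoA -> methylmalonyl-CoA assimilation, reversible
  succinyl-CoA <-> methylmalonyl-CoA isomerisation, malonyl-CoA from
  acetyl-CoA, a 6 methylmalonyl-CoA + 1 malonyl-CoA polyketide synthase,
  biomass and maintenance). Analytic optima and sweep breakpoints are
  derived from the designed stoichiometry with exact rational arithmetic
  and stored in :class:`GroundTruth` — never taken from the LP solver.
* :func:`inject_defects` — seeded curation defects (imbalance, duplicate,
  dead end, wrong direction, orphan) with labels, for QC recall scoring.
* :func:`make_timeseries` — fed-batch concentration trajectories generated
  from a known rate panel, optionally with multiplicative noise.

Carrier moieties use placeholder element symbols (X = coenzyme A scaffold,
Z = NAD(H), W = NADP(H)) so that every non-boundary reaction is exactly
balanced while the lumped pathways stay small. The biomass drain removes a
C4H7NO2 monomer at 1000/131 mmol per unit growth rate, i.e. exactly
1000/32.75 mmol biomass carbon per gDCW — the factor used by the carbon
recovery statistic.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, List, Optional, Tuple

from .gpr import parse_gpr
from .model import Gene, MetabolicModel, Metabolite, Reaction
from .recovery import MOLAR_MASSES, FermentationSeries, RatePanel

DEFAULT_SEED = 20220601

#: n-propanol feed rate (g/L/h) per fermentation mode, active from 60 h
MODE_FEEDS = {"CK": 0.0, "mode1": 0.025, "mode2": 0.05, "mode3": 0.075}

DEFECT_KINDS = ("unbalance", "duplicate", "dead_end", "wrong_direction", "orphan")


@dataclass
class SyntheticSpec:
    """Reproducible parameters for every generator (fixed seed => identical output)."""

    seed: int = DEFAULT_SEED
    # toy-network options
    maintenance_atp: bool = False
    maintenance_flux: float = 1.0  # mmol ATP/gDCW/h forced when maintenance on
    isozyme_pairs: int = 1  # reactions (glycolysis first) given OR-isozymes
    extra_parallel_path: bool = False  # second, longer erythromycin export route
    o2_cap: Optional[float] = None  # cap |O2 uptake|; adds a lactate overflow branch
    glucose_uptake: float = 10.0  # default medium glucose bound (mmol/gDCW/h)
    propanol_uptake: float = 10.0  # default medium propanol bound
    sweep_glucose: float = 0.1  # canonical glucose budget for robustness sweeps
    # defect injection
    defects: Dict[str, int] = field(default_factory=dict)
    # fed-batch series options
    mode: str = "CK"
    noise_sd: float = 0.0  # multiplicative gaussian SD fraction
    duration_h: float = 144.0
    cadence_h: float = 12.0
    dcw0: float = 10.0  # g/L
    glucose0: float = 80.0  # g/L
    propanol0: float = 4.0  # g/L residual pool at the start of supplementation

    def __post_init__(self):
        if self.mode not in MODE_FEEDS:
            raise ValueError(f"unknown fermentation mode {self.mode!r}")
        for kind in self.defects:
            if kind not in DEFECT_KINDS:
                raise ValueError(f"unknown defect kind {kind!r}")
        if not 0 <= self.isozyme_pairs <= 3:
            raise ValueError("isozyme_pairs must be 0..3")


@dataclass
class GroundTruth:
    """Closed-form reference values derived from the designed stoichiometry.

    All values come from hand yield arithmetic over the lumped network
    (recorded as exact fractions), so LP results can be tested against an
    independent oracle. Optima are None for variants (O2 cap) where the
    closed forms do not apply.
    """

    glucose_uptake: float
    propanol_uptake: float
    mu_max: Optional[float]  # default medium (glucose + propanol open)
    mu_max_glucose_only: Optional[float]  # sole-carbon glucose medium
    qery_max: Optional[float]  # growth-free erythromycin optimum, default medium
    qery_max_glucose_only: Optional[float]
    essential_genes: FrozenSet[str]  # sole-glucose medium, growth objective
    atp_per_glucose: float = 28.0  # full aerobic oxidation
    atp_per_propanol: float = 18.0
    # propanol sweep (erythromycin objective, glucose budget = sweep_glucose)
    sweep_glucose: float = 0.1
    sweep_rise_slope: float = float(Fraction(12, 125))
    sweep_mid_slope: float = float(Fraction(6, 89))
    sweep_r1: float = 0.0  # end of the first linear segment
    sweep_r2: float = 0.0  # start of the plateau
    sweep_plateau_qery: float = 0.0
    sweep_baseline_qery: float = 0.0  # qEry at zero propanol
    propanol_limited_slope: float = float(Fraction(1, 6))
    biomass_carbon_per_mu: float = 1000.0 / 32.75


def _met(mid, name, formula, compartment, charge=0):
    return Metabolite(id=mid, name=name, formula=formula, charge=charge, compartment=compartment)


def _toy_metabolites(extra_parallel_path: bool, with_overflow: bool) -> List[Metabolite]:
    mets = [
        # extracellular
        _met("glc__D_e", "D-glucose", "C6H12O6", "e"),
        _met("ppoh_e", "n-propanol", "C3H8O", "e"),
        _met("o2_e", "oxygen", "O2", "e"),
        _met("co2_e", "carbon dioxide", "CO2", "e"),
        _met("h2o_e", "water", "H2O", "e"),
        _met("nh3_e", "ammonia", "H3N", "e"),
        _met("ery_e", "erythromycin A", "C37H67NO13", "e"),
        _met("xyl__D_e", "D-xylose (no assimilation route)", "C5H10O5", "e"),
        _met("no3_e", "nitrate (no assimilation route)", "NO3", "e"),
        # cytosol
        _met("glc__D_c", "D-glucose", "C6H12O6", "c"),
        _met("ppoh_c", "n-propanol", "C3H8O", "c"),
        _met("pyr_c", "pyruvate", "C3H4O3", "c"),
        _met("accoa_c", "acetyl-CoA", "C2H3OX", "c"),
        _met("coa_c", "coenzyme A", "HX", "c"),
        _met("oaa_c", "oxaloacetate", "C4H4O5", "c"),
        _met("succoa_c", "succinyl-CoA", "C4H5O3X", "c"),
        _met("mmcoa_c", "methylmalonyl-CoA", "C4H5O3X", "c"),
        _met("ppcoa_c", "propionyl-CoA", "C3H5OX", "c"),
        _met("malcoa_c", "malonyl-CoA", "C3H3O3X", "c"),
        _met("nad_c", "NAD carrier (oxidised)", "Z", "c"),
        _met("nadh_c", "NAD carrier (reduced)", "H2Z", "c"),
        _met("nadp_c", "NADP carrier (oxidised)", "W", "c"),
        _met("nadph_c", "NADP carrier (reduced)", "H2W", "c"),
        _met("atp_c", "ATP", "C10H16N5O13P3", "c"),
        _met("adp_c", "ADP", "C10H15N5O10P2", "c"),
        _met("pi_c", "phosphate", "H3O4P", "c"),
        _met("h2o_c", "water", "H2O", "c"),
        _met("co2_c", "carbon dioxide", "CO2", "c"),
        _met("o2_c", "oxygen", "O2", "c"),
        _met("nh3_c", "ammonia", "H3N", "c"),
        _met("ery_c", "erythromycin A", "C37H67NO13", "c"),
        _met("bm_c", "biomass monomer", "C4H7NO2", "c"),
    ]
    if extra_parallel_path:
        mets.append(_met("eryx_c", "carrier-bound erythromycin", "C37H67NO13", "c"))
    if with_overflow:
        mets += [
            _met("lac__L_c", "L-lactate", "C3H6O3", "c"),
            _met("lac__L_e", "L-lactate", "C3H6O3", "e"),
            _met("pacet_c", "propyl acetate", "C5H10O2", "c"),
            _met("pacet_e", "propyl acetate", "C5H10O2", "e"),
        ]
    return mets


def _rxn(rid, name, stoich, lb, ub, gpr="", subsystem=None, kind="metabolic"):
    return Reaction(
        id=rid, name=name, stoichiometry=dict(stoich), lower_bound=lb, upper_bound=ub,
        gpr=parse_gpr(gpr), subsystem=subsystem, kind=kind,
    )


def make_toy_model(spec: SyntheticSpec = SyntheticSpec()) -> Tuple[MetabolicModel, GroundTruth]:
    """Build the lumped erythromycin-producer network and its ground truth."""
    with_overflow = spec.o2_cap is not None
    B = 1000.0  # bound proxy
    G, P = spec.glucose_uptake, spec.propanol_uptake

    # OR-isozyme pairs are granted in this order
    iso = {"GLY": spec.isozyme_pairs >= 1, "PDH": spec.isozyme_pairs >= 2, "TCA1": spec.isozyme_pairs >= 3}

    def gpr_for(tag: str) -> str:
        return f"g{tag}1 or g{tag}2" if iso.get(tag) else f"g{tag}"

    bm = float(Fraction(1000, 131))  # biomass monomers per unit mu (C4 each)
    bm_glc = float(Fraction(2000, 393))
    bm_h2o = float(Fraction(3240, 131))
    gam = 40.0  # growth-associated ATP, mmol/gDCW

    reactions = [
        # exchanges (uptake = negative flux)
        _rxn("EX_glc__D_e", "glucose exchange", {"glc__D_e": -1}, -G, B, kind="exchange"),
        _rxn("EX_ppoh_e", "n-propanol exchange", {"ppoh_e": -1}, -P, B, kind="exchange"),
        _rxn("EX_o2_e", "O2 exchange", {"o2_e": -1},
             -(spec.o2_cap if spec.o2_cap is not None else B), B, kind="exchange"),
        _rxn("EX_co2_e", "CO2 exchange", {"co2_e": -1}, -B, B, kind="exchange"),
        _rxn("EX_h2o_e", "water exchange", {"h2o_e": -1}, -B, B, kind="exchange"),
        _rxn("EX_nh3_e", "ammonia exchange", {"nh3_e": -1}, -B, B, kind="exchange"),
        _rxn("EX_ery_e", "erythromycin exchange", {"ery_e": -1}, 0, B, kind="exchange"),
        _rxn("EX_xyl__D_e", "xylose exchange", {"xyl__D_e": -1}, -10, B, kind="exchange"),
        _rxn("EX_no3_e", "nitrate exchange", {"no3_e": -1}, -10, B, kind="exchange"),
        _rxn("DM_bm_c", "biomass drain", {"bm_c": -1}, 0, B, kind="exchange"),
        # transport
        _rxn("GLCt", "glucose transport", {"glc__D_e": -1, "glc__D_c": 1}, 0, B,
             gpr="gGLCt", subsystem="Transport", kind="transport"),
        _rxn("PPOHt", "propanol transport", {"ppoh_e": -1, "ppoh_c": 1}, 0, B,
             gpr="gPPOHt", subsystem="Transport", kind="transport"),
        _rxn("NH3t", "ammonia transport", {"nh3_e": -1, "nh3_c": 1}, 0, B,
             gpr="gNH3t", subsystem="Transport", kind="transport"),
        _rxn("O2t", "O2 diffusion", {"o2_e": -1, "o2_c": 1}, -B, B,
             subsystem="Transport", kind="spontaneous"),
        _rxn("CO2t", "CO2 diffusion", {"co2_c": -1, "co2_e": 1}, -B, B,
             subsystem="Transport", kind="spontaneous"),
        _rxn("H2Ot", "water diffusion", {"h2o_c": -1, "h2o_e": 1}, -B, B,
             subsystem="Transport", kind="spontaneous"),
        _rxn("ERYt", "erythromycin export", {"ery_c": -1, "ery_e": 1}, 0, B,
             gpr="gERYt", subsystem="Transport", kind="transport"),
        # central carbon metabolism (lumped, exactly balanced)
        _rxn("GLY", "glycolysis (lumped)",
             {"glc__D_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
              "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2},
             0, B, gpr=gpr_for("GLY"), subsystem="Glycolysis"),
        _rxn("PPP", "pentose phosphate pathway (lumped, NADPH source)",
             {"glc__D_c": -1, "nadp_c": -12, "h2o_c": -6, "co2_c": 6, "nadph_c": 12},
             0, B, gpr="gPPP", subsystem="Pentose phosphate pathway"),
        _rxn("PDH", "pyruvate dehydrogenase",
             {"pyr_c": -1, "coa_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
             0, B, gpr=gpr_for("PDH"), subsystem="TCA cycle"),
        _rxn("PC", "pyruvate carboxylase",
             {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
              "oaa_c": 1, "adp_c": 1, "pi_c": 1},
             0, B, gpr="gPC", subsystem="TCA cycle"),
        _rxn("TCA1", "citrate synthase to succinyl-CoA (lumped)",
             {"accoa_c": -1, "oaa_c": -1, "nad_c": -2, "h2o_c": -1,
              "succoa_c": 1, "co2_c": 2, "nadh_c": 2},
             0, B, gpr=gpr_for("TCA1"), subsystem="TCA cycle"),
        _rxn("TCA2", "succinyl-CoA to oxaloacetate (lumped)",
             {"succoa_c": -1, "adp_c": -1, "pi_c": -1, "nad_c": -2, "h2o_c": -1,
              "oaa_c": 1, "coa_c": 1, "atp_c": 1, "nadh_c": 2},
             0, B, gpr="gTCA2", subsystem="TCA cycle"),
        _rxn("OAADC", "oxaloacetate decarboxylase", {"oaa_c": -1, "pyr_c": 1, "co2_c": 1},
             0, B, gpr="gOAADC", subsystem="TCA cycle"),
        _rxn("OXPHOS", "oxidative phosphorylation (P/O = 2)",
             {"nadh_c": -2, "o2_c": -1, "adp_c": -4, "pi_c": -4,
              "nad_c": 2, "atp_c": 4, "h2o_c": 6},
             0, B, gpr="gOXP", subsystem="Oxidative phosphorylation"),
        # propanol assimilation and precursor supply
        _rxn("PPOHDH", "propanol -> propionyl-CoA (lumped dehydrogenase/ligase)",
             {"ppoh_c": -1, "coa_c": -1, "nad_c": -2, "atp_c": -1, "h2o_c": -1,
              "ppcoa_c": 1, "nadh_c": 2, "adp_c": 1, "pi_c": 1},
             0, B, gpr="gPPOH", subsystem="Methylmalonyl-CoA pathway"),
        _rxn("PCC", "propionyl-CoA carboxylase",
             {"ppcoa_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
              "mmcoa_c": 1, "adp_c": 1, "pi_c": 1},
             0, B, gpr="gPCC", subsystem="Methylmalonyl-CoA pathway"),
        _rxn("MUT", "methylmalonyl-CoA mutase (reversible isomerisation)",
             {"mmcoa_c": -1, "succoa_c": 1}, -B, B,
             gpr="gMUT", subsystem="Methylmalonyl-CoA pathway"),
        _rxn("ACC", "acetyl-CoA carboxylase",
             {"accoa_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
              "malcoa_c": 1, "adp_c": 1, "pi_c": 1},
             0, B, gpr="gACC", subsystem="Erythromycin biosynthesis"),
        # 6 methylmalonyl-CoA + 1 malonyl-CoA per erythromycin A; the sugar
        # arm (2 glucose) and NADPH demand make the PP pathway indispensable
        # for production. Two condensation CO2 leave 37 carbons.
        _rxn("ERYS", "erythromycin synthase (lumped PKS + glycosylation)",
             {"mmcoa_c": -6, "malcoa_c": -1, "glc__D_c": -2, "nh3_c": -1, "nadph_c": -23,
              "ery_c": 1, "coa_c": 7, "co2_c": 2, "nadp_c": 23, "h2o_c": 16},
             0, B, gpr="gERYS1 and gERYS2", subsystem="Erythromycin biosynthesis"),
        # growth: 1000/131 C4H7NO2 monomers per unit mu = 1000/32.75 mmol C/gDCW
        _rxn("BIOMASS", "biomass synthesis",
             {"glc__D_c": -bm_glc, "nh3_c": -bm, "atp_c": -gam, "h2o_c": -bm_h2o,
              "bm_c": bm, "adp_c": gam, "pi_c": gam},
             0, B, subsystem="Biomass", kind="biomass"),
        _rxn("ATPM", "non-growth maintenance ATP drain",
             {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
             spec.maintenance_flux if spec.maintenance_atp else 0.0, B,
             subsystem="Maintenance"),
    ]
    if spec.extra_parallel_path:
        reactions += [
            _rxn("ERYBP1", "erythromycin carrier loading", {"ery_c": -1, "eryx_c": 1},
                 0, B, gpr="gERYBP", subsystem="Transport"),
            _rxn("ERYBP2", "carrier-bound erythromycin export", {"eryx_c": -1, "ery_e": 1},
                 0, B, gpr="gERYBP", subsystem="Transport", kind="transport"),
        ]
    if with_overflow:
        reactions += [
            _rxn("LDH", "lactate dehydrogenase (fermentative overflow)",
                 {"pyr_c": -1, "nadh_c": -1, "lac__L_c": 1, "nad_c": 1},
                 0, B, gpr="gLDH", subsystem="Overflow metabolism"),
            _rxn("LACt", "lactate export", {"lac__L_c": -1, "lac__L_e": 1}, 0, B,
                 subsystem="Transport", kind="spontaneous"),
            _rxn("EX_lac__L_e", "lactate exchange", {"lac__L_e": -1}, 0, B, kind="exchange"),
            # redox-free propanol disposal; consumes glucose-derived acetyl-CoA,
            # which is what makes forced over-supplementation costly under an
            # oxygen cap (the decline regime of the robustness curve)
            _rxn("PESTER", "alcohol acetyltransferase (ester overflow)",
                 {"ppoh_c": -1, "accoa_c": -1, "pacet_c": 1, "coa_c": 1},
                 0, B, gpr="gPESTER", subsystem="Overflow metabolism"),
            _rxn("PACETt", "propyl acetate export", {"pacet_c": -1, "pacet_e": 1}, 0, B,
                 subsystem="Transport", kind="spontaneous"),
            _rxn("EX_pacet_e", "propyl acetate exchange", {"pacet_e": -1}, 0, B, kind="exchange"),
        ]

    model = MetabolicModel(
        model_id="toy_ery",
        metabolites=_toy_metabolites(spec.extra_parallel_path, with_overflow),
        reactions=reactions,
        objective={"BIOMASS": 1.0},
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    model.validate()
    return model, _ground_truth(spec, with_overflow, iso)


def _ground_truth(spec: SyntheticSpec, with_overflow: bool, iso: Dict[str, bool]) -> GroundTruth:
    """Closed-form optima; see the derivations in the inline comments."""
    G = Fraction(spec.glucose_uptake).limit_denominator(10**9)
    P = Fraction(spec.propanol_uptake).limit_denominator(10**9)
    M = Fraction(spec.maintenance_flux).limit_denominator(10**9) if spec.maintenance_atp else Fraction(0)

    # biomass: 2000/393 glc + 40 ATP per unit mu; ATP yields: 28/glc, 18/ppoh.
    bm_glc = Fraction(2000, 393)
    gam = Fraction(40)

    mu_max = mu_max_glc = qery_max = qery_max_glc = None
    if not with_overflow and spec.o2_cap is None:
        # sole glucose: G = mu*bm_glc + g_burn, gam*mu + M = 28*g_burn
        mu_max_glc = (28 * G - M) / (gam + 28 * bm_glc)
        if mu_max_glc < 0:
            mu_max_glc = Fraction(0)
        # default medium: propanol ATP (18*P) covers gam*mu + M, all glucose to biomass
        mu_candidate = G / bm_glc
        if gam * mu_candidate + M <= 18 * P:
            mu_max = mu_candidate
        else:  # propanol ATP short: burn glucose for the remainder
            mu_max = (28 * G + 18 * P - M) / (gam + 28 * bm_glc)
        # erythromycin at mu = 0: per ery 2 glc (sugar) + 23/12 glc (NADPH)
        # + (13e - 2r)/2 glc (13 pyruvate: 12 for six succinyl-CoA-derived
        # extender units, 1 for malonyl-CoA), r = propanol-derived extenders.
        # Segment slopes vs r: 12/125 (glucose-substituting), 6/89, 0.
        def qery_at(budget: Fraction, r_avail: Fraction) -> Fraction:
            r1 = 72 * budget / 53
            r2 = 84 * budget / 47
            r = min(r_avail, r2)
            if r <= r1:
                return 12 * (budget + r) / 125
            return 12 * (budget + r / 2) / 89

        qery_max = qery_at(G, P)
        qery_max_glc = 12 * G / 125

    # essential reactions on sole-glucose growth; with the fermentative
    # overflow branch present, respiration becomes dispensable.
    essential_reactions = ["GLCt", "NH3t", "GLY"] if with_overflow else [
        "GLCt", "NH3t", "GLY", "PDH", "TCA1", "OXPHOS"
    ]
    essential = set()
    for tag_rxn, tag in (("GLCt", "GLCt"), ("NH3t", "NH3t"), ("GLY", "GLY"),
                         ("PDH", "PDH"), ("TCA1", "TCA1"), ("OXPHOS", "OXP")):
        if tag_rxn in essential_reactions and not iso.get(tag_rxn, False):
            essential.add(f"g{tag}")
    # isozyme-paired reactions are never single-gene essential
    for tag_rxn, tag in (("GLY", "GLY"), ("PDH", "PDH"), ("TCA1", "TCA1")):
        if iso.get(tag_rxn, False):
            essential.discard(f"g{tag}")

    S = Fraction(spec.sweep_glucose).limit_denominator(10**9)
    return GroundTruth(
        glucose_uptake=spec.glucose_uptake,
        propanol_uptake=spec.propanol_uptake,
        mu_max=None if mu_max is None else float(mu_max),
        mu_max_glucose_only=None if mu_max_glc is None else float(mu_max_glc),
        qery_max=None if qery_max is None else float(qery_max),
        qery_max_glucose_only=None if qery_max_glc is None else float(qery_max_glc),
        essential_genes=frozenset(essential),
        sweep_glucose=float(S),
        sweep_r1=float(72 * S / 53),
        sweep_r2=float(84 * S / 47),
        sweep_plateau_qery=float(12 * S / 47),
        sweep_baseline_qery=float(12 * S / 125),
    )


def propanol_limited_variant(model: MetabolicModel, glucose_uptake: float = 1.0) -> MetabolicModel:
    """Configuration in which propanol is the sole methylmalonyl-CoA source.

    The succinyl-CoA <-> methylmalonyl-CoA isomerisation is locked to the
    TCA direction and glucose is generous relative to the sweep range, so
    the marginal value of propanol for erythromycin is exactly one sixth
    (six extender units per molecule).
    """
    out = model.copy()
    out.reactions["MUT"].lower_bound = 0.0  # mmcoa -> succoa only
    out.reactions["EX_glc__D_e"].lower_bound = -abs(glucose_uptake)
    return out


def toy_dg_table(model: MetabolicModel) -> Dict[str, float]:
    """Ground-truth standard transformed Gibbs energies for the toy network.

    Designed-irreversible interior reactions are strongly exergonic
    (-50 kJ/mol), designed-reversible ones sit inside the +/-30 band
    (-5 kJ/mol); boundary reactions carry no entry.
    """
    table = {}
    for rxn in model.reactions.values():
        if rxn.kind == "exchange":
            continue
        table[rxn.id] = -5.0 if rxn.reversible else -50.0
    return table


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def inject_defects(
    model: MetabolicModel, spec: SyntheticSpec
) -> Tuple[MetabolicModel, Dict[str, List[str]]]:
    """Apply the spec'd curation defects to seed-chosen targets.

    Returns the defective model and labels mapping defect kind to the
    affected reaction/metabolite ids. Raises ValueError when the requested
    counts cannot be satisfied by the base model.
    """
    rng = random.Random(spec.seed)
    out = model.copy()
    labels: Dict[str, List[str]] = {k: [] for k in DEFECT_KINDS}

    counts = dict(spec.defects)

    # unbalance: delete one proton (or one water) from a balanced reaction
    n = counts.get("unbalance", 0)
    candidates = sorted(
        r.id
        for r in out.reactions.values()
        if r.kind not in ("exchange",)
        and ("h_c" in r.stoichiometry or "h2o_c" in r.stoichiometry)
        and len(r.stoichiometry) >= 3
    )
    if n > len(candidates):
        raise ValueError(f"cannot inject {n} imbalances: only {len(candidates)} candidates")
    for rid in rng.sample(candidates, n):
        rxn = out.reactions[rid]
        species = "h_c" if "h_c" in rxn.stoichiometry else "h2o_c"
        coeff = rxn.stoichiometry[species]
        new = coeff - 1.0 if coeff > 0 else coeff + 1.0
        if new == 0.0:
            del rxn.stoichiometry[species]
        else:
            rxn.stoichiometry[species] = new
        labels["unbalance"].append(rid)

    # duplicate: clone a reaction under a fresh id (GPR kept, reported not
    # merged); skip reactions already unbalanced so each defect stays
    # independently attributable
    n = counts.get("duplicate", 0)
    candidates = sorted(
        r.id
        for r in out.reactions.values()
        if r.kind != "exchange" and r.id not in labels["unbalance"]
    )
    if n > len(candidates):
        raise ValueError(f"cannot inject {n} duplicates")
    for k, rid in enumerate(rng.sample(candidates, n)):
        clone = out.reactions[rid].copy()
        clone.id = f"{rid}__dup{k}"
        clone.name = f"duplicate of {rid}"
        out.add_reaction(clone)
        labels["duplicate"].append(clone.id)

    # dead end: a produced-only metabolite behind a new source reaction
    for k in range(counts.get("dead_end", 0)):
        mid = f"deadend{k}_c"
        out.add_metabolite(_met(mid, "accumulating intermediate", "C3H4O3", "c"))
        out.add_reaction(
            _rxn(f"DEADSRC{k}", f"source of {mid}", {"pyr_c": -1, mid: 1}, 0, 1000.0)
        )
        labels["dead_end"].append(mid)

    # wrong direction: flip a designed-irreversible interior reaction
    n = counts.get("wrong_direction", 0)
    candidates = sorted(
        r.id
        for r in out.reactions.values()
        if r.kind in ("metabolic", "transport")
        and not r.reversible
        and r.upper_bound > 0
        and not r.id.startswith("DEADSRC")
        and "__dup" not in r.id  # clones carry no Gibbs-energy entry
    )
    if n > len(candidates):
        raise ValueError(f"cannot inject {n} direction flips")
    for rid in rng.sample(candidates, n):
        rxn = out.reactions[rid]
        rxn.lower_bound, rxn.upper_bound = -rxn.upper_bound, -rxn.lower_bound
        labels["wrong_direction"].append(rid)

    # orphan: declared but never referenced
    for k in range(counts.get("orphan", 0)):
        mid = f"orphan{k}_c"
        out.add_metabolite(_met(mid, "unreferenced species", "C2H6O", "c"))
        labels["orphan"].append(mid)

    return out, {k: v for k, v in labels.items() if v}


# ---------------------------------------------------------------------------
# fed-batch time series
# ---------------------------------------------------------------------------

def make_timeseries(spec: SyntheticSpec, true_panel: RatePanel) -> FermentationSeries:
    """Integrate a fed-batch trajectory from a known rate panel.

    DCW grows exponentially at the panel's mu; concentrations change
    linearly within each sampling interval at the panel's specific rates
    against the interval-mean DCW (the same trapezoid the rate estimator
    inverts, so the zero-noise round trip is exact). Multiplicative
    gaussian noise of fraction ``noise_sd`` is applied per sample.
    """
    rng = random.Random(spec.seed)
    feed = MODE_FEEDS[spec.mode]
    n_steps = int(round(spec.duration_h / spec.cadence_h))
    times = [i * spec.cadence_h for i in range(n_steps + 1)]

    dcw = [spec.dcw0 * math.exp(true_panel.mu * t) for t in times]
    glucose = [spec.glucose0]
    propanol = [spec.propanol0]
    ery = [0.0]
    co2 = [0.0]
    for i in range(n_steps):
        t0, t1 = times[i], times[i + 1]
        dt = t1 - t0
        x_mean = 0.5 * (dcw[i] + dcw[i + 1])
        # propanol feeding and metabolism both start at 60 h
        feed_overlap = max(0.0, t1 - max(t0, 60.0))
        g = glucose[-1] - true_panel.q_glucose * x_mean * dt * MOLAR_MASSES["glucose"] / 1000.0
        p = (
            propanol[-1]
            + feed * feed_overlap
            - true_panel.q_propanol * x_mean * feed_overlap * MOLAR_MASSES["propanol"] / 1000.0
        )
        e = ery[-1] + true_panel.q_ery * x_mean * dt * MOLAR_MASSES["erythromycin"]
        c = co2[-1] + true_panel.q_co2 * x_mean * dt
        if g < 0 or p < 0:
            raise ValueError(
                f"substrate exhausted at {t1} h (glucose {g:.3f} g/L, propanol {p:.3f} g/L): "
                "rates too high for the initial concentrations"
            )
        glucose.append(g)
        propanol.append(p)
        ery.append(e)
        co2.append(c)

    def noisy(values: List[float]) -> List[float]:
        if spec.noise_sd <= 0:
            return list(values)
        return [max(0.0, v * (1.0 + rng.gauss(0.0, spec.noise_sd))) for v in values]

    return FermentationSeries(
        times=times,
        dcw=noisy(dcw),
        glucose=noisy(glucose),
        propanol=noisy(propanol),
        erythromycin=noisy(ery),
        co2_cumulative=noisy(co2),
        propanol_feed_g_per_l_h=feed,
        feed_start_h=60.0,
        mode=spec.mode,
    )
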