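"""LP core: FBA, media, variability, parsimonious fluxes, duals.

The small-network oracle enumerates polytope vertices by brute force
(fix n - rank(S) bounds, solve the square system), independently of the
LP solver.
"""

import itertools

import numpy as np
import pytest

from erygem import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    build_stoichiometric_matrix,
    flux_variability,
    parsimonious_flux,
    solve_fba,
    verify_solution,
)
from erygem.fba import total_absolute_flux
from erygem.synth import SyntheticSpec, make_toy_model


def chain_model():
    """EX_a (uptake <= 10) -> a -> b -> biomass-like sink."""
    return MetabolicModel(
        model_id="chain",
        metabolites=[Metabolite("a_c", compartment="c"), Metabolite("b_c", compartment="c")],
        reactions=[
            Reaction("EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-10, upper_bound=0,
                     kind="exchange"),
            Reaction("AB", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=1000),
            Reaction("SINK_b", stoichiometry={"b_c": -1.0}, upper_bound=1000, kind="exchange"),
        ],
        objective={"SINK_b": 1.0},
    )


def brute_force_optimum(model: MetabolicModel, objective) -> float:
    """Vertex enumeration oracle for networks with few degrees of freedom."""
    S, met_idx, rxn_idx = build_stoichiometric_matrix(model)
    S = S.toarray()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    c = np.zeros(n)
    for rid, w in objective.items():
        c[rxn_idx[rid]] = w
    best = None
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(choice)
            A = S[:, free]
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.max(np.abs(A @ sol - rhs)) > 1e-8:
                continue
            v = np.zeros(n)
            v[list(fixed)] = choice
            v[free] = sol
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                z = float(c @ v)
                best = z if best is None else max(best, z)
    return best


def test_single_path_chain():
    sol = solve_fba(chain_model())
    assert sol.optimal
    assert sol.objective_value == pytest.approx(10.0, abs=1e-8)
    assert sol.fluxes["EX_a"] == pytest.approx(-10.0, abs=1e-8)


def test_solver_matches_vertex_enumeration_on_branched_network():
    """Two routes with different yields: the LP must find the enumerated optimum."""
    model = MetabolicModel(
        model_id="branch",
        metabolites=[Metabolite(m, compartment="c") for m in ("a_c", "b_c", "c_c")],
        reactions=[
            Reaction("EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-5, upper_bound=0,
                     kind="exchange"),
            Reaction("R1", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=3),
            Reaction("R2", stoichiometry={"a_c": -2.0, "b_c": 1.0, "c_c": 1.0}, upper_bound=1000),
            Reaction("SINK_b", stoichiometry={"b_c": -1.0}, upper_bound=1000, kind="exchange"),
            Reaction("SINK_c", stoichiometry={"c_c": -1.0}, upper_bound=1000, kind="exchange"),
        ],
        objective={"SINK_b": 1.0},
    )
    expected = brute_force_optimum(model, {"SINK_b": 1.0})
    sol = solve_fba(model)
    assert sol.objective_value == pytest.approx(expected, abs=1e-8)


def test_toy_erythromycin_optimum_matches_independent_solver(toy_model, ground_truth):
    """Cross-check the erythromycin optimum against cobrapy on the same network."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("toy")
    cm.add_metabolites(
        [cobra.Metabolite(m.id, compartment=m.compartment) for m in toy_model.metabolites.values()]
    )
    for r in toy_model.reactions.values():
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({cm.metabolites.get_by_id(m): c for m, c in r.stoichiometry.items()})
    cm.objective = "EX_ery_e"
    cobra_opt = cm.slim_optimize()
    ours = solve_fba(toy_model, objective={"EX_ery_e": 1.0}).objective_value
    assert ours == pytest.approx(cobra_opt, rel=1e-6)
    assert ours == pytest.approx(ground_truth.qery_max, rel=1e-9)


def test_infeasible_reported_not_raised():
    model = chain_model()
    model.reactions["AB"].lower_bound = 5.0  # forced flux
    model.reactions["EX_a"].lower_bound = 0.0  # but no substrate
    sol = solve_fba(model)
    assert sol.status == "infeasible"


def test_solution_certificates(toy_model):
    sol = solve_fba(toy_model)
    resid = verify_solution(toy_model, sol)
    assert resid["mass_balance_rel"] <= 1e-6
    assert resid["bound_violation"] <= 1e-9
    assert resid["duality_gap_rel"] <= 1e-6


def test_apply_medium_sole_carbon(toy_model):
    medium = Medium(sole_carbon=True, bounds={"EX_glc__D_e": (-10.0, 1000.0)})
    out = apply_medium(toy_model, medium)
    assert out.reactions["EX_glc__D_e"].lower_bound == -10.0
    # other organic uptakes closed, inorganic gases left free
    assert out.reactions["EX_xyl__D_e"].lower_bound == 0.0
    assert out.reactions["EX_ppoh_e"].lower_bound == 0.0
    assert out.reactions["EX_o2_e"].lower_bound == -1000.0
    assert out.reactions["EX_co2_e"].lower_bound == -1000.0


def test_apply_empty_medium_is_identity(toy_model):
    out = apply_medium(toy_model, Medium())
    for rid, rxn in toy_model.reactions.items():
        assert (out.reactions[rid].lower_bound, out.reactions[rid].upper_bound) == (
            rxn.lower_bound, rxn.upper_bound,
        )


def test_medium_naming_non_exchange_reaction_errors(toy_model):
    with pytest.raises(ValueError, match="non-exchange"):
        apply_medium(toy_model, Medium(bounds={"GLY": (0.0, 1.0)}))
    with pytest.raises(KeyError):
        apply_medium(toy_model, Medium(bounds={"EX_nothing": (0.0, 1.0)}))


def test_medium_tsv_round_trip(tmp_path):
    medium = Medium(sole_carbon=True, bounds={"EX_glc__D_e": (-10.0, 1000.0)})
    medium.to_tsv(tmp_path / "medium.tsv")
    again = Medium.from_tsv(tmp_path / "medium.tsv")
    assert again.sole_carbon and again.bounds == medium.bounds


def test_fva_unique_path_min_equals_max():
    ranges = flux_variability(chain_model(), objective_fraction=1.0)
    for rid, (lo, hi) in ranges.items():
        assert lo == pytest.approx(hi, abs=1e-7), rid
        assert abs(lo) == pytest.approx(10.0, abs=1e-7)


def test_fva_isolated_cycle_is_blocked():
    model = MetabolicModel(
        model_id="cycle",
        metabolites=[Metabolite("a_c"), Metabolite("b_c")],
        reactions=[
            Reaction("F", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=1000),
            Reaction("G", stoichiometry={"b_c": -1.0, "a_c": 1.0}, upper_bound=1000),
        ],
        objective={"F": 1.0},
    )
    # a 2-cycle with no boundary can spin, but with any dead-end tap it cannot
    model.reactions["F"].stoichiometry["c_c"] = 1.0
    model.add_metabolite(Metabolite("c_c"))
    ranges = flux_variability(model, objective_fraction=0.0)
    assert ranges["F"] == (pytest.approx(0.0, abs=1e-7), pytest.approx(0.0, abs=1e-7))
    assert ranges["G"] == (pytest.approx(0.0, abs=1e-7), pytest.approx(0.0, abs=1e-7))


def test_fva_ranges_nested_by_objective_fraction(toy_model):
    free = flux_variability(toy_model, objective_fraction=0.0)
    locked = flux_variability(toy_model, objective_fraction=1.0)
    for rid in toy_model.reactions:
        assert locked[rid][0] >= free[rid][0] - 1e-6
        assert locked[rid][1] <= free[rid][1] + 1e-6


def test_parsimonious_suppresses_futile_cycle():
    model = chain_model()
    # add a futile cycle parallel to the optimal path
    model.add_reaction(Reaction("LOOP1", stoichiometry={"a_c": -1.0, "b_c": 1.0},
                                lower_bound=-1000, upper_bound=1000))
    sol = parsimonious_flux(model)
    assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
    # flux splits arbitrarily in plain FBA; pFBA must not cycle AB vs LOOP1
    assert abs(sol.fluxes["AB"]) + abs(sol.fluxes["LOOP1"]) <= 10.0 + 1e-6


def test_parsimonious_equals_fba_on_unique_optimum():
    base = solve_fba(chain_model())
    pars = parsimonious_flux(chain_model())
    for rid in base.fluxes:
        assert pars.fluxes[rid] == pytest.approx(base.fluxes[rid], abs=1e-7)


def test_parsimonious_picks_shorter_of_two_equal_yield_paths():
    """The direct export beats the two-step carrier route on total |v|."""
    model, _ = make_toy_model(SyntheticSpec(extra_parallel_path=True))
    sol = parsimonious_flux(model, objective={"EX_ery_e": 1.0})
    assert sol.fluxes["ERYBP1"] == pytest.approx(0.0, abs=1e-7)
    assert sol.fluxes["ERYt"] == pytest.approx(sol.fluxes["EX_ery_e"], abs=1e-6)
    # hand-computed minimum total flux: rerouting x through the carrier adds x
    direct = total_absolute_flux(sol)
    alt = solve_fba(model, objective={"EX_ery_e": 1.0})
    assert direct <= total_absolute_flux(alt) + 1e-6


def test_bound_sensitivity_matches_finite_difference(toy_model):
    """Dual of the glucose uptake bound vs central difference of the optimum."""
    base = solve_fba(toy_model, objective={"EX_ery_e": 1.0})
    sens = base.bound_sensitivities["EX_glc__D_e"]
    h = 1e-3
    z = {}
    for delta in (-h, h):
        m = toy_model.copy()
        m.reactions["EX_glc__D_e"].lower_bound = -10.0 + delta
        z[delta] = solve_fba(m, objective={"EX_ery_e": 1.0}).objective_value
    fd = (z[h] - z[-h]) / (2 * h)
    assert sens == pytest.approx(fd, abs=1e-6)
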