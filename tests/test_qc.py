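"""Curation QC: balance, fixes, duplicates, connectivity, directionality."""

import pytest

from erygem import (
    DirectionalityRule,
    MetabolicModel,
    Metabolite,
    Reaction,
    assign_directionality,
    check_balance,
    directionality_conflicts,
    find_blocked,
    find_dead_ends,
    find_duplicates,
    propose_balance_fix,
    propose_exchanges,
    run_qc,
)
from erygem.qc import BalanceFinding


def hexokinase_model(drop_proton=False):
    """glc + ATP -> G6P + ADP + H+ with real formulas and charges."""
    model = MetabolicModel(
        model_id="hex",
        metabolites=[
            Metabolite("glc__D_c", formula="C6H12O6", charge=0),
            Metabolite("atp_c", formula="C10H12N5O13P3", charge=-4),
            Metabolite("g6p_c", formula="C6H11O9P", charge=-2),
            Metabolite("adp_c", formula="C10H12N5O10P2", charge=-3),
            Metabolite("h_c", formula="H", charge=1),
            Metabolite("h2o_c", formula="H2O", charge=0),
        ],
        reactions=[
            Reaction(
                "HEX1",
                stoichiometry={
                    "glc__D_c": -1.0, "atp_c": -1.0,
                    "g6p_c": 1.0, "adp_c": 1.0, **({} if drop_proton else {"h_c": 1.0}),
                },
                upper_bound=1000,
            )
        ],
    )
    return model


def test_textbook_hexokinase_is_balanced():
    findings = check_balance(hexokinase_model())
    assert findings[0].status == "balanced"


def test_missing_proton_detected_and_fixed():
    """Dropping the product proton leaves {H:-1, charge:-1}: add 1 proton to products."""
    model = hexokinase_model(drop_proton=True)
    finding = check_balance(model)[0]
    assert finding.status == "imbalanced"
    assert finding.element_imbalance == {"H": -1.0}
    assert finding.charge_imbalance == pytest.approx(-1.0)
    assert finding.proposed_fix == [("products", "proton", 1)]
    fixed = propose_balance_fix(model, finding)
    model.reactions["HEX1"].stoichiometry = fixed.stoichiometry
    assert check_balance(model)[0].status == "balanced"


def test_unknown_formula_is_indeterminate_not_crash():
    model = hexokinase_model()
    model.metabolites["g6p_c"].formula = None
    assert check_balance(model)[0].status == "indeterminate"


def test_missing_water_fix():
    """Imbalance {O:-1, H:-2} (products short one water) -> add 1 water to products."""
    model = hexokinase_model()
    model.reactions["HEX1"].stoichiometry["h2o_c"] = -1.0  # spurious reactant water
    finding = check_balance(model)[0]
    assert finding.status == "imbalanced"
    assert finding.proposed_fix == [("products", "water", 1)]
    fixed = propose_balance_fix(model, finding)
    model.reactions["HEX1"].stoichiometry = fixed.stoichiometry
    assert check_balance(model)[0].status == "balanced"


def test_carbon_imbalance_has_no_proton_water_fix():
    model = hexokinase_model()
    del model.reactions["HEX1"].stoichiometry["g6p_c"]  # carbon leaves unmatched
    finding = check_balance(model)[0]
    assert finding.status == "imbalanced"
    assert finding.proposed_fix is None
    assert propose_balance_fix(model, finding) is None


def test_propose_fix_requires_imbalanced_finding():
    with pytest.raises(ValueError):
        propose_balance_fix(hexokinase_model(), BalanceFinding("HEX1", status="balanced"))


def test_exchanges_skipped_by_balance_check(toy_model):
    ids = {f.reaction_id for f in check_balance(toy_model)}
    assert not any(toy_model.reactions[rid].kind == "exchange" for rid in ids)


def _two_rxn_model(r1: Reaction, r2: Reaction):
    mets = {m for r in (r1, r2) for m in r.stoichiometry}
    return MetabolicModel(
        metabolites=[Metabolite(m) for m in sorted(mets)], reactions=[r1, r2]
    )


def test_duplicates_exact():
    m = _two_rxn_model(
        Reaction("R1", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=10),
        Reaction("R2", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=99),
    )
    assert find_duplicates(m) == [["R1", "R2"]]


def test_duplicates_antiparallel_with_mirrored_bounds():
    m = _two_rxn_model(
        Reaction("F", stoichiometry={"a_c": -1.0, "b_c": 1.0}, lower_bound=-3, upper_bound=10),
        Reaction("B", stoichiometry={"a_c": 1.0, "b_c": -1.0}, lower_bound=-10, upper_bound=3),
    )
    assert find_duplicates(m) == [["B", "F"]]


def test_scaled_stoichiometry_is_not_duplicate():
    m = _two_rxn_model(
        Reaction("R1", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=10),
        Reaction("R2", stoichiometry={"a_c": -2.0, "b_c": 2.0}, upper_bound=10),
    )
    assert find_duplicates(m) == []


def test_dead_end_and_orphan_detection():
    model = MetabolicModel(
        metabolites=[Metabolite(m) for m in ("a_c", "b_c", "c_c", "lost_c")],
        reactions=[
            Reaction("SRC", stoichiometry={"a_c": 1.0}, upper_bound=10, kind="exchange"),
            Reaction("AB", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=10),
        ],
    )
    dead, orphans = find_dead_ends(model)
    assert dead == ["b_c"] and set(orphans) == {"c_c", "lost_c"}
    # a reversible consumer whose partner is consumed downstream clears b
    model.add_reaction(Reaction("BC", stoichiometry={"b_c": -1.0, "c_c": 1.0},
                                lower_bound=-10, upper_bound=10))
    model.add_reaction(Reaction("SINK_c", stoichiometry={"c_c": -1.0}, upper_bound=10,
                                kind="exchange"))
    dead, orphans = find_dead_ends(model)
    assert dead == [] and orphans == ["lost_c"]


def test_clean_toy_model_has_empty_qc_report(toy_model):
    from erygem.synth import toy_dg_table

    report = run_qc(toy_model, dg_table=toy_dg_table(toy_model))
    assert report.is_clean()
    assert report.imbalanced == []
    assert report.duplicate_groups == []
    assert report.dead_ends == [] and report.orphans == []
    assert report.directionality_conflicts == []


def test_blocked_reactions_and_exchange_proposal_unblocks(fresh_toy, glucose_medium):
    """A dead-end metabolite blocks its pathway; a demand reaction unblocks it."""
    model, _ = fresh_toy
    model.add_metabolite(Metabolite("waste_c", formula="C3H4O3", charge=0, compartment="c"))
    model.add_reaction(Reaction("MKWASTE", stoichiometry={"pyr_c": -1.0, "waste_c": 1.0},
                                upper_bound=1000))
    blocked = find_blocked(model, glucose_medium)
    assert "MKWASTE" in blocked
    proposals = propose_exchanges(model)
    assert [p.id for p in proposals] == ["DM_waste_c"]
    assert (proposals[0].lower_bound, proposals[0].upper_bound) == (0.0, 1000.0)
    for p in proposals:
        model.add_reaction(p)
    unblocked = find_blocked(model, glucose_medium)
    assert "MKWASTE" not in unblocked
    # monotonicity: adding an exchange never increases the blocked set
    assert set(unblocked) <= set(blocked)


def test_biomass_path_not_blocked(toy_model, glucose_medium):
    blocked = set(find_blocked(toy_model, glucose_medium))
    for rid in ("GLCt", "GLY", "BIOMASS", "DM_bm_c", "EX_glc__D_e"):
        assert rid not in blocked


def test_propose_exchanges_skips_existing_and_extracellular(fresh_toy):
    model, _ = fresh_toy
    assert propose_exchanges(model) == []  # no dead ends in the clean network
    model.add_metabolite(Metabolite("junk_e", formula="C2H6O", charge=0, compartment="e"))
    model.add_reaction(Reaction("JUNKt", stoichiometry={"h2o_c": -1.0, "junk_e": 1.0},
                                upper_bound=1000))
    proposals = propose_exchanges(model)
    assert [p.id for p in proposals] == ["EX_junk_e"]


@pytest.mark.parametrize(
    "dg,expected",
    [(-45.0, "forward_only"), (-10.0, "reversible"), (30.0, "reversible"),
     (-30.0, "reversible"), (45.0, "reverse_only")],
)
def test_directionality_threshold_rule(dg, expected):
    model = _two_rxn_model(
        Reaction("R1", stoichiometry={"a_c": -1.0, "b_c": 1.0}, lower_bound=-10, upper_bound=10),
        Reaction("R2", stoichiometry={"b_c": -1.0, "a_c": 1.0}, lower_bound=-10, upper_bound=10),
    )
    assignments = assign_directionality(model, {"R1": dg}, DirectionalityRule())
    assert assignments["R1"] == expected
    assert assignments["R2"] == "unassigned"
    if expected == "forward_only":
        assert model.reactions["R1"].lower_bound == 0.0
    if expected == "reverse_only":
        assert model.reactions["R1"].upper_bound == 0.0
    # untouched when absent from the table
    assert model.reactions["R2"].lower_bound == -10


def test_directionality_conflict_flags_flipped_reaction(fresh_toy):
    from erygem.synth import toy_dg_table

    model, _ = fresh_toy
    dg = toy_dg_table(model)
    assert directionality_conflicts(model, dg) == []
    rxn = model.reactions["PCC"]
    rxn.lower_bound, rxn.upper_bound = -rxn.upper_bound, -rxn.lower_bound
    assert directionality_conflicts(model, dg) == ["PCC"]


def test_qc_report_serialises(toy_model, tmp_path):
    report = run_qc(toy_model)
    report.to_json(tmp_path / "qc.json")
    report.to_tsv(tmp_path / "qc.tsv")
    assert (tmp_path / "qc.json").read_text().startswith("{")
    assert "category" in (tmp_path / "qc.tsv").read_text()
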