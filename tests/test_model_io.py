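"""Model structures, stoichiometric matrix and dialect round-trips."""

import math

import pytest

from erygem import (
    Gene,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    build_stoichiometric_matrix,
    load_model,
    parse_formula,
    save_model,
)
from erygem.gpr import parse_gpr
from erygem.io import ModelParseError, parse_equation


def tiny_model():
    return MetabolicModel(
        model_id="tiny",
        metabolites=[
            Metabolite("a_c", formula="C3H6O3", charge=0, compartment="c"),
            Metabolite("b_c", formula="C3H6O3", charge=0, compartment="c"),
        ],
        reactions=[
            Reaction("EX_a", stoichiometry={"a_c": -1.0}, lower_bound=-10, upper_bound=1000,
                     kind="exchange"),
            Reaction("AB", stoichiometry={"a_c": -1.0, "b_c": 1.0}, upper_bound=1000,
                     gpr=parse_gpr("g1 or g2")),
            Reaction("EX_b", stoichiometry={"b_c": -1.0}, upper_bound=1000, kind="exchange"),
        ],
        objective={"EX_b": 1.0},
    )


def test_formula_parsing():
    assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
    assert parse_formula("C10H16N5O13P3") == {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3}
    assert parse_formula("H2Z") == {"H": 2, "Z": 1}  # placeholder carrier symbols
    with pytest.raises(ValueError):
        parse_formula("C6H12O6)")


def test_counts_and_matrix_shape():
    model = tiny_model()
    assert model.summary() == {"genes": 2, "reactions": 3, "metabolites": 2}
    S, met_idx, rxn_idx = build_stoichiometric_matrix(model)
    assert S.shape == (2, 3)
    assert S[met_idx["a_c"], rxn_idx["AB"]] == -1
    assert S[met_idx["b_c"], rxn_idx["AB"]] == 1
    # exchange column: a single -1 entry
    col = S[:, rxn_idx["EX_a"]].toarray().ravel()
    assert list(col) == [-1, 0]


def test_matrix_nonzeros_equal_total_stoichiometry(toy_model):
    S, _, _ = build_stoichiometric_matrix(toy_model)
    expected = sum(len(r.stoichiometry) for r in toy_model.reactions.values())
    assert S.nnz == expected


def test_erythromycin_synthase_precursor_column(toy_model):
    """Six extender and one starter unit per erythromycin molecule."""
    S, met_idx, rxn_idx = build_stoichiometric_matrix(toy_model)
    j = rxn_idx["ERYS"]
    assert S[met_idx["mmcoa_c"], j] == -6
    assert S[met_idx["malcoa_c"], j] == -1


def test_dangling_metabolite_reference_is_named():
    model = tiny_model()
    model.reactions["AB"].stoichiometry["ghost_c"] = 1.0
    with pytest.raises(ModelStructureError, match="ghost_c"):
        model.validate()


def test_dangling_gene_reference_is_named():
    model = tiny_model()
    model.reactions["AB"].gpr = parse_gpr("g1 or g_missing")
    model.genes.pop("g_missing", None)
    with pytest.raises(ModelStructureError, match="g_missing"):
        model.validate()


def test_exchange_must_touch_one_metabolite():
    rxn = Reaction("EX_bad", stoichiometry={"a_c": -1.0, "b_c": 1.0}, kind="exchange")
    with pytest.raises(ModelStructureError, match="exactly one"):
        rxn.validate()


def test_equation_parser():
    assert parse_equation("2 a_c + b_c -> c_c") == {"a_c": -2.0, "b_c": -1.0, "c_c": 1.0}
    assert parse_equation("a_c <=> b_c") == {"a_c": -1.0, "b_c": 1.0}
    assert parse_equation("glc_e ->") == {"glc_e": -1.0}
    with pytest.raises(ModelParseError):
        parse_equation("a_c b_c", "R1")


def _assert_structurally_equal(a: MetabolicModel, b: MetabolicModel, coeff_rel=0.0):
    assert a.summary() == b.summary()
    assert list(a.reactions) == list(b.reactions)
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        assert set(ra.stoichiometry) == set(rb.stoichiometry), rid
        for mid, ca in ra.stoichiometry.items():
            cb = rb.stoichiometry[mid]
            if coeff_rel:
                assert math.isclose(ca, cb, rel_tol=coeff_rel), (rid, mid)
            else:
                assert ca == cb, (rid, mid)
        assert math.isclose(ra.lower_bound, rb.lower_bound, rel_tol=1e-12)
        assert math.isclose(ra.upper_bound, rb.upper_bound, rel_tol=1e-12)
        assert ra.kind == rb.kind, rid
        assert parse_gpr(ra.gpr.to_string()).root == parse_gpr(rb.gpr.to_string()).root, rid
    for mid, ma in a.metabolites.items():
        mb = b.metabolites[mid]
        assert (ma.formula, ma.charge, ma.compartment) == (mb.formula, mb.charge, mb.compartment)
    assert a.objective == b.objective


@pytest.mark.parametrize("dialect,filename", [
    ("json", "toy.json"),
    ("sbml3", "toy.xml"),
    ("tsv", "toy_dir"),
])
def test_round_trip_all_dialects(toy_model, tmp_path, dialect, filename):
    path = tmp_path / filename
    save_model(toy_model, path, dialect=dialect)
    again = load_model(path)  # dialect sniffed
    # SBML serialises doubles at ~15 significant digits; the contract is >= 12
    _assert_structurally_equal(toy_model, again, coeff_rel=1e-12)


def test_rational_coefficients_survive_round_trip(tmp_path):
    model = tiny_model()
    model.reactions["AB"].stoichiometry["a_c"] = -1.0 / 3.0
    model.reactions["AB"].stoichiometry["b_c"] = 2.0 / 3.0
    for name in ("m.json", "m.xml", "m_dir"):
        save_model(model, tmp_path / name)
        again = load_model(tmp_path / name)
        got = again.reactions["AB"].stoichiometry["a_c"]
        assert math.isclose(got, -1.0 / 3.0, rel_tol=1e-12), name


def test_empty_gpr_round_trips(tmp_path):
    model = tiny_model()
    model.reactions["AB"].gpr = parse_gpr("")
    save_model(model, tmp_path / "m.json")
    again = load_model(tmp_path / "m.json")
    assert again.reactions["AB"].gpr.is_empty


def test_malformed_json_names_problem(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text("{not json")
    with pytest.raises(ModelParseError):
        load_model(p)


def test_undeclared_metabolite_in_file_is_structural_error(tmp_path):
    p = tmp_path / "bad2.json"
    p.write_text(
        '{"metabolites": [{"id": "a_c"}], "genes": [],'
        ' "reactions": [{"id": "R1", "stoich": {"a_c": -1, "phantom_c": 1}, "lb": 0, "ub": 10}],'
        ' "objective": {}}'
    )
    with pytest.raises(ModelStructureError, match="phantom_c"):
        load_model(p)
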