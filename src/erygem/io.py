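"""Model readers and writers.

Three dialects:

* ``sbml3`` — SBML Level 3 core + fbc v2 (bounds, gene products, objective),
  the community exchange format for constraint-based models. Standard
  ``M_``/``R_``/``G_`` id prefixes are stripped on read and added on write.
* ``json`` — a compact dialect with top-level keys ``metabolites``,
  ``reactions``, ``genes``, ``objective``, ``compartments``; each reaction
  carries ``stoich`` (map), ``lb``, ``ub``, ``gpr`` (string) and ``kind``.
* ``tsv`` — a reactions table (id, equation with ``->``/``<=>``, lb, ub,
  gpr) plus a metabolites table (id, name, formula, charge, compartment).
  A path may be a directory holding ``reactions.tsv``/``metabolites.tsv``
  or the reactions file itself with the metabolites file alongside.

``load_model`` sniffs the dialect from the path/content when not named.
"""

from __future__ import annotations

import json
import logging
import math
import re
from pathlib import Path
from typing import Dict, Optional, Tuple

from .gpr import EMPTY_RULE, GPRRule, parse_gpr
from .model import (
    DEFAULT_BOUND,
    Gene,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    infer_reaction_kind,
)

log = logging.getLogger(__name__)

_NUM_FMT = "%.15g"  # >= 12 significant digits for rational coefficients

_NOTES_SUBSYSTEM = re.compile(r"subsystem: ([^<]+)")


class ModelParseError(ValueError):
    """Unreadable or malformed model file; message names the offending entity."""


# ---------------------------------------------------------------------------
# dialect sniffing
# ---------------------------------------------------------------------------

def sniff_dialect(path) -> str:
    p = Path(path)
    if p.is_dir():
        return "tsv"
    suffix = p.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml3"
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    head = p.read_bytes()[:200].lstrip()
    if head.startswith(b"<"):
        return "sbml3"
    if head.startswith(b"{"):
        return "json"
    return "tsv"


def load_model(path, dialect: Optional[str] = None) -> MetabolicModel:
    """Read a model file, validate it and report its census.

    Raises :class:`ModelParseError` on malformed content and
    :class:`~erygem.model.ModelStructureError` on dangling references.
    """
    dialect = dialect or sniff_dialect(path)
    if dialect == "sbml3":
        model = _read_sbml(path)
    elif dialect == "json":
        model = _read_json(path)
    elif dialect == "tsv":
        model = _read_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.validate()
    s = model.summary()
    log.info(
        "loaded %s (%s): %d genes, %d reactions, %d metabolites",
        path, dialect, s["genes"], s["reactions"], s["metabolites"],
    )
    return model


def save_model(model: MetabolicModel, path, dialect: Optional[str] = None):
    """Write *model*; ``load_model(save_model(m))`` is structurally identical."""
    dialect = dialect or sniff_dialect_for_save(path)
    model.validate()
    if dialect == "sbml3":
        _write_sbml(model, path)
    elif dialect == "json":
        _write_json(model, path)
    elif dialect == "tsv":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def sniff_dialect_for_save(path) -> str:
    p = Path(path)
    if p.suffix.lower() in (".xml", ".sbml"):
        return "sbml3"
    if p.suffix.lower() == ".json":
        return "json"
    return "tsv"


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _read_json(path) -> MetabolicModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON ({exc})") from exc
    model = MetabolicModel(model_id=doc.get("id", Path(path).stem))
    for comp, name in (doc.get("compartments") or {}).items():
        model.compartments[comp] = name
    for m in doc.get("metabolites", []):
        try:
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                    compartment=m.get("compartment", "c"),
                )
            )
        except KeyError as exc:
            raise ModelParseError(f"{path}: metabolite entry missing {exc}") from exc
    for g in doc.get("genes", []):
        model.add_gene(Gene(id=g["id"], name=g.get("name")))
    for r in doc.get("reactions", []):
        try:
            rxn = Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r.get("lb", 0.0)),
                upper_bound=float(r.get("ub", DEFAULT_BOUND)),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem"),
                kind=r.get("kind", "metabolic"),
            )
        except KeyError as exc:
            raise ModelParseError(f"{path}: reaction entry missing {exc}") from exc
        if "kind" not in r:
            rxn.kind = infer_reaction_kind(rxn, model)
        model.add_reaction(rxn)
    model.objective = {k: float(v) for k, v in (doc.get("objective") or {}).items()}
    return model


def _write_json(model: MetabolicModel, path):
    doc = {
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        "genes": [
            {"id": g.id, **({"name": g.name} if g.name else {})}
            for g in model.genes.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": dict(r.stoichiometry),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                **({"gpr": r.gpr.to_string()} if not r.gpr.is_empty else {}),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
        "objective": dict(model.objective),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _tsv_paths(path, for_write: bool = False) -> Tuple[Path, Path]:
    p = Path(path)
    if p.is_dir() or (for_write and not p.suffix):
        if for_write:
            p.mkdir(parents=True, exist_ok=True)
        return p / "reactions.tsv", p / "metabolites.tsv"
    name = p.name
    if "reactions" in name:
        return p, p.with_name(name.replace("reactions", "metabolites"))
    return p, p.with_name(p.stem + ".metabolites.tsv")


def format_equation(rxn: Reaction) -> str:
    """Render stoichiometry as ``a A + b B -> c C`` (``<=>`` if reversible)."""
    lhs, rhs = [], []
    for mid, coeff in rxn.stoichiometry.items():
        target = rhs if coeff > 0 else lhs
        mag = abs(coeff)
        term = mid if mag == 1 else f"{_NUM_FMT % mag} {mid}"
        target.append(term)
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def parse_equation(text: str, rxn_id: str = "?") -> Dict[str, float]:
    """Parse ``2 A + B -> C`` / ``A <=> B`` into a stoichiometry map."""
    for arrow in ("<=>", "<->", "-->", "->", "="):
        if arrow in text:
            lhs_text, rhs_text = text.split(arrow, 1)
            break
    else:
        raise ModelParseError(f"reaction {rxn_id}: equation {text!r} has no arrow")
    stoich: Dict[str, float] = {}

    def add_side(side_text: str, sign: float):
        side_text = side_text.strip()
        if not side_text:
            return
        for term in side_text.split("+"):
            term = term.strip()
            if not term:
                raise ModelParseError(f"reaction {rxn_id}: empty term in {text!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, mid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError as exc:
                    raise ModelParseError(
                        f"reaction {rxn_id}: bad coefficient {parts[0]!r}"
                    ) from exc
                mid = parts[1]
            else:
                raise ModelParseError(f"reaction {rxn_id}: bad term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff
            if stoich[mid] == 0.0:
                del stoich[mid]

    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    return stoich


def _read_tsv(path) -> MetabolicModel:
    import csv

    rxn_path, met_path = _tsv_paths(path)
    model = MetabolicModel(model_id=Path(rxn_path).stem)
    if met_path.exists():
        with open(met_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                charge = row.get("charge", "")
                model.add_metabolite(
                    Metabolite(
                        id=row["id"],
                        name=row.get("name", ""),
                        formula=row.get("formula") or None,
                        charge=int(charge) if charge not in ("", None) else None,
                        compartment=row.get("compartment", "c"),
                    )
                )
    with open(rxn_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            stoich = parse_equation(row["equation"], row["id"])
            reversible = "<=>" in row["equation"] or "<->" in row["equation"]
            lb_text, ub_text = row.get("lb", ""), row.get("ub", "")
            lb = float(lb_text) if lb_text else (-DEFAULT_BOUND if reversible else 0.0)
            ub = float(ub_text) if ub_text else DEFAULT_BOUND
            for mid in stoich:
                if mid not in model.metabolites:
                    # metabolites table may be absent for quick fixtures
                    if met_path.exists():
                        raise ModelStructureError(
                            f"reaction {row['id']} references undeclared metabolite {mid}"
                        )
                    comp = mid.rsplit("_", 1)[-1] if "_" in mid else "c"
                    model.add_metabolite(Metabolite(id=mid, compartment=comp))
            rxn = Reaction(
                id=row["id"],
                name=row.get("name", ""),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(row.get("gpr", "")),
                subsystem=row.get("subsystem") or None,
                kind=row.get("kind") or "metabolic",
            )
            if not row.get("kind"):
                rxn.kind = infer_reaction_kind(rxn, model)
            model.add_reaction(rxn)
            obj = row.get("objective", "")
            if obj:
                model.objective[rxn.id] = float(obj)
    return model


def _write_tsv(model: MetabolicModel, path):
    import csv

    rxn_path, met_path = _tsv_paths(path, for_write=True)
    with open(met_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "name", "formula", "charge", "compartment"])
        for m in model.metabolites.values():
            w.writerow(
                [m.id, m.name, m.formula or "", "" if m.charge is None else m.charge, m.compartment]
            )
    with open(rxn_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "name", "equation", "lb", "ub", "gpr", "subsystem", "kind", "objective"])
        for r in model.reactions.values():
            w.writerow(
                [
                    r.id,
                    r.name,
                    format_equation(r),
                    _NUM_FMT % r.lower_bound,
                    _NUM_FMT % r.upper_bound,
                    r.gpr.to_string(),
                    r.subsystem or "",
                    r.kind,
                    model.objective.get(r.id, ""),
                ]
            )


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------

def _strip_prefix(sid: str, prefix: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no <model> element")
    fbc = sbml_model.getPlugin("fbc")

    model = MetabolicModel(model_id=sbml_model.getId() or Path(path).stem)
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are the environment, not model content
        sp_fbc = sp.getPlugin("fbc")
        formula = charge = None
        if sp_fbc is not None:
            if sp_fbc.isSetChemicalFormula():
                formula = sp_fbc.getChemicalFormula() or None
            if sp_fbc.isSetCharge():
                charge = sp_fbc.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_strip_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment() or "c",
            )
        )

    gene_label: Dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or _strip_prefix(gp.getId(), "G_")
            gene_label[gp.getId()] = label
            model.add_gene(Gene(id=label, name=gp.getName() or None))

    def parameter_value(pid: str, default: float) -> float:
        par = sbml_model.getParameter(pid) if pid else None
        return par.getValue() if par is not None else default

    def association_to_text(assoc) -> str:
        import libsbml as _ls

        if assoc is None:
            return ""
        code = assoc.getTypeCode()
        if code == _ls.SBML_FBC_GENEPRODUCTREF:
            return gene_label.get(assoc.getGeneProduct(), assoc.getGeneProduct())
        parts = [
            association_to_text(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        joiner = " and " if code == _ls.SBML_FBC_AND else " or "
        return "(" + joiner.join(parts) + ")"

    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        r_fbc = sr.getPlugin("fbc")
        stoich: Dict[str, float] = {}
        skipped_boundary = False
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            sp = sbml_model.getSpecies(ref.getSpecies())
            if sp is not None and sp.getBoundaryCondition():
                skipped_boundary = True
                continue
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            sp = sbml_model.getSpecies(ref.getSpecies())
            if sp is not None and sp.getBoundaryCondition():
                skipped_boundary = True
                continue
            mid = _strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        reversible = sr.getReversible()
        if r_fbc is not None and r_fbc.isSetLowerFluxBound():
            lb = parameter_value(r_fbc.getLowerFluxBound(), -DEFAULT_BOUND)
            ub = parameter_value(r_fbc.getUpperFluxBound(), DEFAULT_BOUND)
        else:
            lb = -DEFAULT_BOUND if reversible else 0.0
            ub = DEFAULT_BOUND
        if math.isinf(lb):
            lb = -DEFAULT_BOUND
        if math.isinf(ub):
            ub = DEFAULT_BOUND
        gpr = EMPTY_RULE
        if r_fbc is not None and r_fbc.isSetGeneProductAssociation():
            text = association_to_text(r_fbc.getGeneProductAssociation().getAssociation())
            gpr = parse_gpr(text)
        rxn = Reaction(
            id=_strip_prefix(sr.getId(), "R_"),
            name=sr.getName() or "",
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
        )
        kind = None
        if sr.isSetNotes():
            notes = sr.getNotesString()
            for k in ("metabolic", "transport", "exchange", "spontaneous", "biomass"):
                if f"kind: {k}" in notes:
                    kind = k
                    break
            sub = _NOTES_SUBSYSTEM.search(notes)
            if sub:
                rxn.subsystem = sub.group(1).strip()
        if kind is not None:
            rxn.kind = kind
        else:
            rxn.kind = "exchange" if skipped_boundary else infer_reaction_kind(rxn, model)
        model.add_reaction(rxn)

    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            model.objective[_strip_prefix(fo.getReaction(), "R_")] = fo.getCoefficient()
    return model


def _write_sbml(model: MetabolicModel, path):
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    m_fbc = sm.getPlugin("fbc")
    m_fbc.setStrict(True)

    for comp_id, comp_name in (model.compartments or {"c": "c"}).items():
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setName(str(comp_name))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId("M_" + met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if met.formula:
            sp_fbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp_fbc.setCharge(int(met.charge))

    for gene in model.genes.values():
        gp = m_fbc.createGeneProduct()
        gp.setId("G_" + gene.id.replace("-", "_"))
        gp.setLabel(gene.id)
        if gene.name:
            gp.setName(gene.name)

    bound_params: Dict[float, str] = {}

    def bound_parameter(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            par.setSBOTerm("SBO:0000626")
            bound_params[value] = pid
        return bound_params[value]

    from .gpr import BoolOp, GeneRef

    def fill_association(parent, node):
        if isinstance(node, GeneRef):
            ref = parent.createGeneProductRef()
            ref.setGeneProduct("G_" + node.gene_id.replace("-", "_"))
        elif isinstance(node, BoolOp):
            sub = parent.createAnd() if node.op == "and" else parent.createOr()
            for child in node.children:
                fill_association(sub, child)
        else:  # pragma: no cover - defensive
            raise TypeError(f"unexpected GPR node {node!r}")

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId("R_" + rxn.id)
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        r_fbc = sr.getPlugin("fbc")
        r_fbc.setLowerFluxBound(bound_parameter(rxn.lower_bound))
        r_fbc.setUpperFluxBound(bound_parameter(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = r_fbc.createGeneProductAssociation()
            fill_association(gpa, rxn.gpr.root)
        if rxn.subsystem or rxn.kind:
            note = (
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>kind: {rxn.kind}</p>"
                + (f"<p>subsystem: {rxn.subsystem}</p>" if rxn.subsystem else "")
                + "</body>"
            )
            sr.setNotes(note)

    if model.objective:
        obj = m_fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid, weight in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction("R_" + rid)
            fo.setCoefficient(float(weight))
        m_fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml_kind_notes(path) -> Dict[str, str]:  # pragma: no cover - helper
    """Best-effort recovery of reaction kinds written into SBML notes."""
    text = Path(path).read_text()
    out = {}
    for m in re.finditer(r'<reaction[^>]*id="R_([^"]+)"(.*?)</reaction>', text, re.S):
        kind = re.search(r"kind: (\w+)", m.group(2))
        if kind:
            out[m.group(1)] = kind.group(1)
    return out
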