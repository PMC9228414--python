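"""Curation QC: find injected defects and propose proton/water repairs.

Five defect kinds are planted into a clean network with ground-truth
labels; the QC report must recover all of them and nothing else.
"""

from erygem import (
    SyntheticSpec,
    check_balance,
    inject_defects,
    make_toy_model,
    propose_balance_fix,
    run_qc,
)
from erygem.synth import toy_dg_table

spec = SyntheticSpec(
    seed=2022,
    defects={"unbalance": 1, "duplicate": 1, "dead_end": 1, "wrong_direction": 1, "orphan": 1},
)
clean, _ = make_toy_model(spec)
defective, labels = inject_defects(clean, spec)
print("injected:", {k: v for k, v in labels.items()})

report = run_qc(defective, dg_table=toy_dg_table(clean))
print("clean model would report  :", run_qc(clean, dg_table=toy_dg_table(clean)).is_clean())
print("imbalanced reactions      :", [f.reaction_id for f in report.imbalanced])
print("duplicate groups          :", report.duplicate_groups)
print("dead-end metabolites      :", report.dead_ends)
print("orphan metabolites        :", report.orphans)
print("direction conflicts (dG)  :", report.directionality_conflicts)

finding = report.imbalanced[0]
print(f"imbalance of {finding.reaction_id}: {finding.element_imbalance} "
      f"charge {finding.charge_imbalance:+g}; proposed fix: {finding.proposed_fix}")
fixed = propose_balance_fix(defective, finding)
defective.reactions[finding.reaction_id].stoichiometry = fixed.stoichiometry
rechecked = {f.reaction_id: f.status for f in check_balance(defective)}
print("amended stoichiometry restores balance:", rechecked[finding.reaction_id] == "balanced")
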