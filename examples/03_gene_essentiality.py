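"""Single-gene deletion screen on a glucose minimal medium.

Each gene is knocked out in turn; reactions whose boolean GPR rule turns
false are constrained to zero flux and growth is re-optimised. A knockout
optimum below 1e-5 1/h marks the gene essential.
"""

from erygem import Medium, SyntheticSpec, make_toy_model, single_gene_deletion

model, truth = make_toy_model(SyntheticSpec())
medium = Medium(sole_carbon=True, bounds={"EX_glc__D_e": (-10.0, 1000.0)})

results = single_gene_deletion(model, medium=medium)
essential = sorted(r.gene_id for r in results if r.classification == "essential")
print(f"{len(essential)} of {len(results)} genes essential on glucose: {essential}")
print("matches generator ground truth:", set(essential) == set(truth.essential_genes))

print("\ngene        knockout mu   disabled reactions")
for r in sorted(results, key=lambda x: x.growth_rate):
    print(f"{r.gene_id:<11} {r.growth_rate:>10.6f}   {','.join(r.disabled_reactions) or '-'}")
print("\nIsozyme pairs (e.g. the two glycolysis genes) stay dispensable: the OR")
print("rule keeps the reaction catalysable when only one partner is deleted.")
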