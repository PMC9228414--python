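statistic	value
total_genes	7714
genes_assigned	1426
effective_genes	1426
total_reactions	1858
unique_reactions	1858
metabolic_reactions	1632
transport_and_exchange_reactions	225
metabolites	1687
gpr_associations	1492
reactions_with_genes	1492
reactions_without_genes	366
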