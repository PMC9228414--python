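source_name	exchange_id	observed
L-Valine	EX_val__L_e	+
L-Threonine	EX_thr__L_e	+
L-Isoleucine	EX_ile__L_e	+
L-Leucine	EX_leu__L_e	+
L-Methionine	EX_met__L_e	+
L-Aspartate	EX_asp__L_e	+
L-Glutamine	EX_gln__L_e	+
L-Phenylalanine	EX_phe__L_e	+
L-Glutamate	EX_glu__L_e	+
L-Serine	EX_ser__L_e	+
L-Proline	EX_pro__L_e	+
Glycine	EX_gly_e	+
L-Lysine	EX_lys__L_e	-
L-Histidine	EX_his__L_e	+
L-Cysteine	EX_cys__L_e	+
L-Asparagine	EX_asn__L_e	+
L-Alanine	EX_ala__L_e	+
L-Arginine	EX_arg__L_e	+
L-Tyrosine	EX_tyr__L_e	-
L-Tryptophan	EX_trp__L_e	+
Urea	EX_urea_e	+
4-Aminobutanoate	EX_4abut_e	+
Xanthine	EX_xan_e	-
Hypoxanthine	EX_hxan_e	-
Ammonium chloride	EX_nh4_e	+
Ammonium nitrate	EX_nh4no3_e	+
Ammonium acetate	EX_nh4ac_e	+
Ammonium oxalate	EX_nh4oxa_e	+
Ammonium carbonate	EX_nh4co3_e	+
Ammonium sulfate	EX_nh4so4_e	+
Ammonium dihydrogen phosphate	EX_nh4h2po4_e	+
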