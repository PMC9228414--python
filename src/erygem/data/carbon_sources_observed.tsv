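source_name	exchange_id	observed
D-Glucose	EX_glc__D_e	+
sucrose	EX_sucr_e	+
D-Xylose	EX_xyl__D_e	+
Mannose	EX_man_e	+
Mannitol	EX_mnl_e	+
L-Rhamnose	EX_rmn_e	+
L-Arabinose	EX_arab__L_e	+
D-Mannose	EX_man__D_e	+
D-Fructose	EX_fru_e	+
Raffinose	EX_raffin_e	+
D-Galactose	EX_gal_e	+
inost	EX_inost_e	+
Melibiose	EX_melib_e	+
D-Ribose	EX_rib__D_e	+
alpha,alpha-Trehalose	EX_tre_e	+
Maltose	EX_malt_e	+
beta-Lactose	EX_lcts__beta_e	+
alpha-Lactose	EX_lcts_e	+
Pyruvate	EX_pyr_e	+
2-Oxoglutarate	EX_akg_e	-
Succinate	EX_succ_e	-
Fumarate	EX_fum_e	-
Acetate	EX_ac_e	+
Propanoate	EX_ppa_e	+
Citrate	EX_cit_e	+
(S)-Malate	EX_mal__L_e	+
(S)-Lactate	EX_lac__L_e	-
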