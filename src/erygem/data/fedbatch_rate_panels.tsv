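quantity	CK	mode1	mode2	mode3
qGlucose	0.219	0.184	0.194	0.150
qPropanol	0	0.073	0.105	0.115
qCO2	0.826	0.837	0.968	0.701
qEry	0.002	0.003	0.003	0.003
qSucCoA	0.013	0.012	0.012	0.014
mu	0.001	0.001	0.002	0.001
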