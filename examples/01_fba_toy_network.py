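"""Flux balance analysis on the bundled toy erythromycin producer.

Builds the lumped network, maximises growth and then erythromycin
secretion, and compares both optima with the closed-form yields stored by
the generator (derived from the stoichiometry by hand, not by the LP).
"""

from erygem import Medium, SyntheticSpec, apply_medium, make_toy_model, solve_fba

model, truth = make_toy_model(SyntheticSpec())
print(model)

# Default medium: glucose and n-propanol both available.
growth = solve_fba(model)
print(f"max growth rate            : {growth.objective_value:.6f} 1/h "
      f"(closed form {truth.mu_max:.6f})")

# Sole-carbon glucose medium: every other organic uptake closed.
glucose_only = apply_medium(
    model, Medium(sole_carbon=True, bounds={"EX_glc__D_e": (-10.0, 1000.0)})
)
mu = solve_fba(glucose_only)
print(f"max growth, glucose only   : {mu.objective_value:.6f} 1/h "
      f"(closed form {truth.mu_max_glucose_only:.6f})")

ery = solve_fba(glucose_only, objective={"EX_ery_e": 1.0})
print(f"max qEry, glucose only     : {ery.objective_value:.6f} mmol/gDCW/h "
      f"(closed form {truth.qery_max_glucose_only:.6f})")

# Dual information: the value of one more unit of glucose uptake capacity.
print(f"glucose shadow price       : {-ery.bound_sensitivities['EX_glc__D_e']:.4f} "
      "mmol erythromycin per extra mmol of glucose uptake")
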