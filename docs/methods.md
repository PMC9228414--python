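# Methods

## Flux balance analysis

The core problem is the standard steady-state LP: maximise cᵀv subject to
S·v = 0 and bounds, solved with scipy's HiGHS interface. Feasibility
tolerance is 10⁻⁹ and dual (optimality) tolerance 10⁻⁸ — ordinary
double-precision LP practice. Every optimal solution carries
certificates: the mass-balance residual ‖S·v‖∞ must stay below
10⁻⁶·max(1, ‖v‖∞), bounds are respected to 10⁻⁹, and a duality-gap check
reconstructs the dual objective from the equality-row duals and reduced
costs (`verify_solution`).

Duals are reported on the maximisation scale: `shadow_prices[m]` is
d z*/d b_m of metabolite m's mass-balance row, and
`bound_sensitivities[r]` is d z*/d(bound value) of whichever bound of
reaction r is active. At a kink of the (concave, piecewise-linear)
optimum the LP dual is one of the subgradients; wherever a derivative is
reported to users (`shadow_price_at`) it is computed by a central finite
difference of step 10⁻³, cross-checked against the dual, and the
right-hand derivative is returned at breakpoints.

Alternate optima are resolved by parsimonious FBA: a second LP over split
variables v = p − q (p, q ≥ 0) minimises Σ(p+q) at the fixed optimal
objective. All reported flux maps route through this step, which makes
them deterministic given the model's reaction order and suppresses futile
cycles. If the equality-pinned second stage is marginally infeasible at
machine precision, the objective row is relaxed by 10⁻⁹ relative.

Bounds use ±1000 mmol/gDCW/h as the conventional "unbounded" proxy;
files that omit bounds get (−1000, 1000) when reversible and (0, 1000)
otherwise.

## Media

A medium is a set of exchange-bound overrides (uptake = negative flux).
In `sole_carbon` mode every other exchange whose metabolite contains
carbon has its uptake closed, except species treated as inorganic
(CO₂/bicarbonate, water, O₂, ammonia/ammonium, phosphate, sulfate,
protons), which remain freely transportable. Carbon screens close
organic-carbon uptakes and leave ammonia open; nitrogen screens close all
nitrogen-containing uptakes (ammonia included) and leave the carbon
source open. The screened source is opened at 10 mmol/gDCW/h — a
conventional microbial uptake scale. Growth calls use a 10⁻⁵ h⁻¹
threshold on the biomass optimum; the same threshold classifies gene
knockouts as essential, since no separate essentiality cut-off is
established and the two questions ("can the model grow") are the same.

## Model QC

Balance checking sums formula elements and charges per reaction
(products minus substrates); exchange reactions are exempt (they are
boundary pseudo-reactions), and a reaction with any participant missing a
formula or charge is *indeterminate* rather than failed. Repair proposals
solve the 2-species integer system over H⁺ (formula H, charge as declared
in the model, canonically +1) and H₂O: the water count is fixed by the O
imbalance, the proton count by the remaining H, and the charge must then
agree; anything else (e.g. a carbon imbalance) is unrepairable by
protons/water and returns null. Every amended reaction re-passes the
balance check by construction.

Duplicates require exactly equal coefficient maps (no scalar-multiple
collapsing, since rescaling changes flux units), or exactly sign-flipped
maps with mirrored bounds (antiparallel duplicates). Dead ends are
metabolites that can only ever be produced or only consumed given current
bounds; orphans appear in no reaction. Blocked reactions are those whose
flux-variability interval is {0} with the objective unconstrained.
Directionality assignment treats reactions as reversible unless the
supplied ΔG°′ exceeds the 30 kJ/mol threshold in magnitude (strict
inequality, so ±30 exactly stays reversible); applying an assignment only
ever tightens bounds. A *conflict* is a reaction whose current bounds
permit only the thermodynamically forbidden direction — this is how
flipped-direction defects are recovered.

## The synthetic erythromycin producer

The generator builds a ~30-reaction lumped network: glucose uptake,
one-step glycolysis (2 ATP + 2 NADH + 2 pyruvate), a cycling
pentose-phosphate lump (12 NADPH per glucose — the sole NADPH source),
pyruvate dehydrogenase, a TCA cycle split at the succinyl-CoA node,
oxidative phosphorylation at P/O = 2, propanol → propionyl-CoA →
methylmalonyl-CoA assimilation, the reversible
succinyl-CoA ↔ methylmalonyl-CoA isomerisation, acetyl-CoA carboxylase,
and a polyketide-synthase lump consuming 6 methylmalonyl-CoA +
1 malonyl-CoA + 2 glucose (the sugar arms) + 23 NADPH per erythromycin A
(C₃₇, with two condensation CO₂ released). Carrier moieties use
placeholder element symbols (X for the CoA scaffold, Z/W for NAD(P)), so
that every interior reaction balances exactly; this is bookkeeping, not
chemistry — the carriers cycle and never cross the boundary.

The biomass reaction drains a C₄H₇NO₂ monomer at 1000/131 mmol per unit
μ, i.e. exactly 1000/32.75 mmol biomass carbon per gDCW — the factor the
carbon-recovery statistic uses — so recovery on any balanced flux vector
closes at 100% exactly. Growth costs 40 mmol ATP/gDCW (a typical
growth-associated maintenance) plus 2000/393 mmol glucose.

All ground truths are derived by hand from this stoichiometry with exact
rational arithmetic at generation time — never from the LP — so solver
tests are non-circular. The key closed forms at glucose budget G and
propanol availability P (mmol/gDCW/h):

* ATP yields: 28 per glucose fully oxidised, 18 per propanol.
* μ_max on sole glucose: (28·G − M)/(40 + 28·2000/393), M the forced
  maintenance flux (0 by default).
* qEry on sole glucose: one erythromycin costs 2 (sugar) + 23/12 (NADPH)
  + 13/2 (thirteen pyruvates: twelve for six TCA-derived extender units,
  one for malonyl-CoA) = 125/12 glucose, hence qEry_max = 12G/125.
* Propanol sweep at fixed G (erythromycin objective, uptake pinned):
  slope 12/125 while glucose substitutes at the margin, 6/89 once
  propanol over-supplies extender units and its surplus substitutes
  pyruvate, then 0; kinks at r₁ = 72G/53 and r₂ = 84G/47, plateau
  qEry = 12G/47.
* Essential genes on sole glucose: the transporters for glucose and
  ammonia, glycolysis (unless given an OR-isozyme pair), pyruvate
  dehydrogenase, the oxidative TCA branch to succinyl-CoA, and oxidative
  phosphorylation. With the fermentative overflow branch present (oxygen-
  capped variant) respiration becomes dispensable and the essential set
  shrinks to the two transporters (+ glycolysis).

Two regimes the default network deliberately does not show:

* **The exact 1/6 shadow price.** With the isomerisation reversible and
  glucose binding, glucose can always substitute for propanol-derived
  methylmalonyl-CoA at 2 pyruvates per unit, so the marginal value of
  propanol is 12/125, not 1/6. The 1/6 value belongs to a strictly
  propanol-limited configuration — generous glucose and the isomerisation
  locked to the TCA direction — exposed as
  `propanol_limited_variant`, where it holds exactly.
* **The decline regime.** With unlimited oxygen, surplus propanol is
  simply respired (it is net ATP-positive), so the sweep plateaus forever
  and a forced ATP drain cannot change that. The decline appears in the
  oxygen-capped variant, which adds two overflow branches: lactate
  (fermentative redox relief) and a propyl-ester condensation that
  disposes of propanol without redox but consumes glucose-derived
  acetyl-CoA. Under a binding O₂ cap, forced over-feeding then drains
  precursor carbon and the shadow price turns negative — the behaviour
  over-supplementation shows in practice. The decline breakpoint is not
  stored in closed form; tests assert it qualitatively (positive →
  zero → negative shadow-price sequence, concavity throughout).

Defect injection plants seeded, labelled curation faults: delete one
proton/water from a balanced reaction (repairable by the proton/water
solver), clone a reaction under a new id, add a produced-only metabolite,
flip a designed-irreversible reaction against its ΔG°′ entry, declare an
unreferenced metabolite. Defects are kept independently attributable
(clones are never taken from already-unbalanced reactions; flips skip
clones, which carry no ΔG entry). A direction flip may strand additional
carrier metabolites — those are genuine secondary dead ends, and recall
tests assert containment for that category and exactness for the rest.
All generator output is bit-reproducible under a fixed seed.

## Fed-batch series and rates

The series generator integrates DCW exponentially at μ and every
concentration linearly per 12-h sampling interval against the
interval-mean DCW; the rate estimator inverts exactly that trapezoid
(two-point secant over the window, mean of the endpoint DCWs,
μ = Δln X/Δt), so the zero-noise round trip is exact and the 2% test
tolerance covers only numerical noise. Propanol feeding *and* metabolism
start at 60 h, matching the supplementation protocol; the estimator
corrects the propanol secant for the known feed rate, without which it
would report net rather than consumed rates. Noise is multiplicative
Gaussian per sample. Defaults (10 g/L DCW, 80 g/L glucose, 4 g/L residual
propanol, 144 h at 12-h cadence) keep all four published rate panels
integrable without substrate exhaustion.

Unit conversions use 180.16 (glucose), 60.10 (propanol) and 733.93 g/mol
(erythromycin A — the titre tables are in µg/mL and need a mass the
source tables do not state). Reported recoveries round half-up to one
decimal; full precision is retained internally. On the control panel the
printed inputs give 95.5506%, a hair past the rounding boundary of the
published 95.5 (evidently computed from unrounded measurements); tests
assert agreement at the printed resolution there and exact rounded
equality for the other three modes.

## Rate-constrained flux maps

`constrained_flux_map` clamps the glucose, propanol, CO₂ and erythromycin
exchanges and the biomass flux to a measured panel within ±5% (the scale
of the reported measurement SDs), maximises erythromycin secretion — the
reported product; the objective the original flux analyses used is not
stated, so this choice is the package's own — and resolves the interior
parsimoniously. On infeasibility the solver reports which single
constraint's relaxation restores feasibility. Pathway aggregates are
sums of |v| per annotated subsystem.

## Scope and limitations

The synthetic network validates the *methods*, not the organism: passing
tests show the LP, QC, screens, sweeps and balances are correct on a
network whose answers are known exactly; they say nothing about the
biology of any particular genome-scale reconstruction. Genome-scale
checks (census, phenotype-screen accuracies) run only when the deposited
reconstruction file is supplied at `data/iJL1426.xml`. Out of scope by
design: MILP gap-filling over a universal reaction database, computing
ΔG°′ from compound structures (consumed as an input table),
loopless/thermodynamic FBA, kinetic simulation of full fermentation
trajectories, isotope-assisted flux analysis, and propanol toxicity
kinetics. Problem sizes throughout (≤ 35 reactions, ≤ 100 seeded LP
instances, 50-seed Monte-Carlo) are chosen so the entire validation suite
runs in seconds on one CPU.
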