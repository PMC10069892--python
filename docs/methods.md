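# Methods

## Model representation and I/O

A model is a list of metabolites (id, compartment, optional Hill-notation
formula, annotations) and reactions (signed stoichiometry, flux bounds in
mmol gDW⁻¹ h⁻¹, EC numbers) plus a linear objective. Exchange reactions
follow the signed single-reaction convention: one reaction per boundary
metabolite, negative flux = import, positive = export. A reaction is
classified as transport when the multiset of metabolite base names (id minus
compartment tag) is identical on both sides; this is what lets pure CO₂
translocation be excluded from production accounting.

SBML reading accepts Level 3 + fbc (bounds as referenced parameters) and the
legacy Level 2 kinetic-law dialect (`LOWER_BOUND`/`UPPER_BOUND` parameters);
reactions with no bounds anywhere default to ±1000 with a logged warning. EC
numbers are harvested with a fixed precedence — MIRIAM `ec-code` CV terms,
then a regex over notes and names, then an optional user mapping table —
because published plant models are annotated inconsistently and all three
sources occur in the wild. Formulas containing generic group symbols (R, X)
are treated as absent: carbon counts are undefined for them, and the
affected metabolites are listed in `skipped_metabolites` of the carbon
fraction so the choice is auditable. The tabular TSV dialect serializes
floats with `repr` and is bit-exact under round trip.

## LP stack

All flux problems run through `scipy.optimize.linprog(method="highs")`
behind a four-method backend interface (load, solve, status, solution);
swapping solvers means overriding one method. Feasibility and optimality
tolerances default to 1e-9 and 1e-6; trait magnitudes below 1e-9 are
reported as 0 since they are below solver resolution.

pFBA splits every reaction with a negative lower bound into two nonnegative
halves and minimizes the total half-flux at a fixed fraction of the FBA
optimum. Because individual fluxes can remain non-unique at the total-flux
optimum, a lexicographic option (default in trait computations and screens)
pins each reaction's absolute flux in reaction-id order after fixing the
total. Each pin carries a 1e-7·(1+|value|) slack: tight enough that reported
traits are stable to ~1e-7, loose enough that the stack of near-equalities
stays feasible for the solver; reactions already at zero are pinned without
a solve (zero is the provable minimum of a nonnegative sum).

The respiration-per-carbon minimum solves
min Σ(producing CO₂ flux) / (carbon fraction · biomass flux) over the whole
polytope by the Charnes–Cooper substitution y = t·v, t ≥ 0, den(y) = 1,
t·lb ≤ y ≤ t·ub. The CO₂-production numerator is direction-aware: a forward
producer contributes through its forward split variable, a reversible
consumer running backward through its reverse one. t* ≤ 1e-12 is reported as
a degenerate program (unbounded growth direction). Tests cross-check the
result against direct bisection on the ratio using independently assembled
LPs.

## CO₂ inventory

CO₂ species are recognized by CHEBI:16526 CV terms, then by formula exactly
"CO2", then by an id/name regex; all compartment instances count. Reactions
are classified per unit forward flux by the sign of their summed CO₂
coefficients; transport and exchange reactions go to an `excluded` map with
a reason. CO₂/bicarbonate interconversions count as production/consumption
by default (they change CO₂ moles); `ignore_bicarbonate` reroutes them to
`excluded` for users who prefer the hydration-equilibrium reading.
Direction-aware accounting (sign of coefficient × flux) happens at the trait
layer, so a reversible carboxylase is booked correctly whichever way it
runs. RuBisCO and the photorespiratory decarboxylation stay in the
producer/consumer sets — the trait layer needs them for A_net — while an
exclusion list allows the stricter biochemical definition that leaves out
photosynthesis and photorespiration entirely.

## Trait panel

All per-distribution traits (A_net, Vc, Vo, Rd, CUE, Rg) come from a single
lexicographic pFBA solution, so CUE = A_net/Vc holds by construction and
printed values are backend-stable. CO₂ exchange fluxes are excluded from
both A_net and Rg (boundary transport, not production); Rnetmax and Anetmax
instead maximize exactly those exchange fluxes (summed when a model has
several CO₂ boundaries) at optimal growth. "Growth respiration" here is the
operational sum of CO₂-releasing fluxes at the reference optimum, not the
growth coefficient g_R of the classical decomposition; the two live in
different modules to avoid conflation. Day/night comparisons solve the day
model first and cap the night model's biomass flux at the day optimum, so
scaled quantities share a reference growth rate.

## Knockout screen

Candidates exclude exchange reactions and the biomass reaction. Each record
is gated by one plain FBA solve (viability: μ ≥ 1e-6 × wild-type μ, which
separates numerically zero growth from slow growth) before the parsimonious
machinery runs; depth-2 pairs where both reactions carry zero wild-type
pFBA flux are pruned and counted (their joint removal provably leaves the
wild-type optimum feasible). Records are ordered lexicographically and the
whole computation is deterministic, so two runs produce identical reports.
Arbitrary explicit knockout sets of any size are supported separately for
probing specific combinations.

## Synthetic photoautotroph

The generator builds a four-compartment miniature of C3 central metabolism:
RuBisCO carboxylation/oxygenation and a lumped Calvin cycle in the
chloroplast; the full photorespiratory salvage loop (phosphoglycolate →
glycolate → glycine → serine → glycerate) spanning chloroplast, peroxisome
and mitochondrion with glycine decarboxylase (EC 1.4.4.2) releasing CO₂ and
ammonia; lumped glycolysis; a TCA cycle with NADP-IDH (1.1.1.42), OGDH
(1.2.4.2), malic enzyme (1.1.1.40) and pyruvate carboxylase anaplerosis; the
oxidative pentose-phosphate decarboxylation (1.1.1.44) feeding ribose-5-P;
linear and cyclic electron flow; oxidative phosphorylation, a
transhydrogenase valve and an ATP-maintenance sink; and a biomass reaction
drawing 3 triose + 1 glycine + 2 ribose-5-P + 8 ATP + 4 NADPH (21 mol C per
unit flux, formula C21H43NO21 so the reaction itself is carbon-closed).

Deliberate simplifications: ATP/NADPH/NADH are carbon-free pseudo-species
shared across compartments (no per-compartment cofactor pools, no ADP/NADP
partners); water and protons are implicit, so hydrogen and oxygen are not
balanced through the lumped energy reactions — carbon and nitrogen are
balanced exactly on every internal reaction and that is what the tests
assert. The ATP-maintenance sink is a single-species reaction and therefore
structurally an exchange of the shared energy pool, which conveniently
keeps it out of the knockout candidate set.

The day optimum is photon-limited and known in closed form (derivation in
the generator docstring): with the oxygenation:carboxylation ratio pinned at
its lower bound 0.31, the photon cost per unit biomass is
(28·Vc + 18·Vo + 32)/3 = 166592/507, i.e. μ* = 507·photon_bound/166592;
without the constraint μ* = 3·photon_bound/704. The night variant closes the
photon exchange and opens a bounded starch (hexose) source; its optimum is
μ* = 13·starch_bound/56, with NADPH supplied by the oxidative
pentose-phosphate route and ATP by oxidizing 8/13 triose per unit biomass
through glycolysis/TCA/oxphos. These rational constants are frozen in the
generator's `GroundTruth` and asserted against the LP to 1e-9 relative.

Default study conditions: photon bound 100, starch bound 10,
ratio window [0.31, 0.55] — ambient-air estimates of the photorespiratory
burden in C3 leaves; wide bounds at ±1000 in the field's customary units.
An optional two-reaction futile cycle with zero net stoichiometry exercises
the pFBA contract (its flux must be exactly 0 under the lexicographic
option). Randomized variants add carbon-balanced bypass reactions between
existing pools, emitting or absorbing compartment-matched CO₂ to close the
balance, with producer/consumer labels derived from the sampled
stoichiometry at generation time.

What the toy does and does not show: it reproduces the *structure* of the
analysis — compartmentalized decarboxylation sources, photorespiration
dominating daytime CO₂ release, oxPPP/TCA dominating dark release, scaled
day respiration exceeding night respiration, no knockout reducing CO₂ per
biomass carbon — but none of the numerical values of any published
genome-scale model. Its flux space is deliberately narrow (near-unique
optima), so passing tests demonstrate correctness of the machinery, not
robustness to the massive alternate-optima degeneracy of real models; the
lexicographic option exists precisely because real models need it. One
consequence of the toy's tightness: at the day optimum photons are exactly
exhausted and CO₂ is the only non-biomass carbon exchange, so the CO₂
exchange flux is pinned at −21μ and Rnetmax = −Anetmax there; the
maximization-dominance behaviour (Rnetmax well above the pFBA Rg) is
exercised on the night model, which has starch slack.

## Classical growth models

The growth–maintenance decomposition and its generalization Σ αᵣ·vᵣ are
direct closed forms. The nitrogen-carbon growth balance
dW/dt = (φ_CN·N_p/k − φ_CN·γ·W − m_R·W)/(1+g_R) is a linear ODE a − bW
integrated with fixed-step RK4, halving the step until the trajectory
matches the exponential closed form to 1e-8 relative (the system is linear
and non-stiff; validation against the closed form is the point, not
integrator sophistication). Units are caller-defined but must be
consistent; trajectories echo the configured time-unit label.

## Numerical choices and degenerate inputs

Ties in contributor rankings break by reaction id. Jaccard similarity of
two empty EC sets is defined as 1 (equal sets). CUE is undefined (None,
flagged) when Vc ≤ 1e-9, e.g. heterotrophs; scaled respiration is undefined
when growth or the carbon fraction is nonpositive (flagged `non-growing`).
A biomass reaction whose carbon-bearing substrates all lack formulas is an
error, not a silent zero. Zero-growth models report traits with μ = 0
rather than failing. Fold changes in knockout records are defined only when
the wild-type quantity is positive, and always against the wild type of the
same constraint regime.

## Known limitations

No gene–protein–reaction rules (knockouts are reaction-level); no flux
sampling or variability beyond the two CO₂-exchange maximizations; no
enzyme-constrained, kinetic or reaction–diffusion formulations; no SBML
groups/layout support, and the SBML writer exists to emit the synthetic
fixtures rather than as a general model-curation tool. The pipeline's
numerical claims about any published model depend on that model's own
bounds and annotations; EC harvesting by regex can pick up spurious matches
in free-text notes, which the precedence order mitigates but cannot
eliminate.
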