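# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical schemes, and what the test suite does and does not
establish.  Units throughout are the model's own arbitrary concentration,
time and value units.

## Model summary and assumptions

The reactor is a constant-volume chemostat: every chemical and every
protocell is washed out at the dilution rate μ.  All individuals of a
protocell type are identical (the standard consumer–resource assumption);
a type is fully described by its diet sets, metabolic weight matrix M,
enzyme levels E, costs, and optionally a regulatory network.  Nutrition is
an "OR" function — uptake rates of different diet nutrients are independent
Monod terms, and there is no co-limitation.  There is no spatial structure,
no explicit membrane or genotype: mutation acts directly on the high-level
attributes (M, E, network weights).

Growth-value bookkeeping makes the model thermodynamically consistent.
Each chemical carries a growth value v_i > 0; a metabolism is admissible iff
every diet nutrient yields strictly positive usable value,
Δv_n = v_n − Σ_i M_{n i} v_i > 0.  This is a concentration-independent
sufficient condition for the requirement that value inflow to any operating
metabolism strictly exceeds its by-product outflow, and it is enforced at
construction, after every mutation (by rejection sampling), and audited
along trajectories in tests.  Defaults: v = 1 for externally fed nutrients,
v = 0.5 for metabolic by-products.

Two distinct enzyme-cost parameters exist and should not be conflated:

* `enzyme_costs` e_n — the metabolic running cost in λ (default 0.1 value
  per enzyme unit per time).  With the default maintenance R = 10, feeds of
  200, budget-face enzymes and Δv = 0.8, this leaves a comfortably viable
  λ ≈ 32 at feed-level concentrations.
* `budget_weights` w_n with cap `E_budget` — the hard constraint
  Σ w_n E_n ≤ E_budget (defaults: unit weights, budget 60), which makes the
  symmetric two-enzyme split exactly 30 units.  A single coefficient cannot
  play both roles: unit *metabolic* costs with budget 60 would make the cost
  term at the face (60) exceed the maximum possible uptake value
  (60·Δv < 60), so every protocell would starve.

## Stochastic engine

Division, washout and starvation are modelled per individual with rates
max(0, gλ), μ and max(0, −gλ); the explicit starvation channel is what makes
the deterministic limit correct for λ < 0.  The engine is a hybrid
tau-leaper: within a step, chemistry and enzymes evolve continuously, and
event counts per (type, channel) are drawn as Poisson variates at frozen
rates, in fixed type-sorted, channel-sorted order from a single seeded PCG64
generator — a (configuration, seed) pair reproduces the event log exactly.
Two refinements matter numerically:

* **Step control.**  Δτ = min(configured Δτ, 0.1·N_total/R_total, T/400 for
  the fastest feed period T), so expected event counts stay below 10% of the
  population and rates change little across a step.
* **Exponential mean-matching.**  Frozen-rate leaping has a first-order
  bias (it compounds 1 − rΔτ instead of e^{−rΔτ}).  All three channel rates
  are scaled by φ = expm1(netΔτ)/(netΔτ), which makes the expected net
  change match the exact linear birth–death mean over the step; for a pure
  death process the mean becomes exact at any Δτ.

Chemicals relax one to two orders of magnitude faster than populations, so
within a step the chemical ODE dc/dt = P(c) − L(c)c (P: feed inflow plus
by-product excretion, L: dilution plus uptake) is solved by a three-cycle
fixed-point iteration for the quasi-steady state followed by exponential
relaxation toward it — A-stable, positivity-preserving, and exact when P and
L are constant; it reduces to explicit Euler when chemicals are slow.  Event
rates use the step-averaged Monod saturation.

Populations are counts n_σ of individuals of biomass b₀ (p_σ = n_σ·b₀).
The default b₀ = 0.02 was set so that the case-study equilibrium biomass
(~1.8 concentration units at feeds of 200) corresponds to populations in the
hundred-individual range, matching the standard initial condition of
n = 100; b₀ is freely configurable, and the convergence tests sweep it.
Poisson overshoot (more deaths drawn than individuals alive) is resolved by
capping deaths at the living, so integer conservation
births − deaths = Δn holds exactly on the event log.

## Regulation

Network: one hidden layer of five tanh nodes; linear output clamped at zero
(production rates cannot be negative, and the all-zero network is then
*exactly* inert, as required for "initially disabled" regulation).  Inputs
are the host's enzyme levels concatenated with its diet-nutrient
concentrations squashed as c/(1+c) — bounded inputs keep the evolving
weights well-scaled.  Whether by-product concentrations the host excretes
(but does not eat) should also be visible to the network is an open
modelling choice; here the network sees exactly the diet.

The floor and budget forcings (ξ_min, ξ_max) are realized as exact
derivative projections: inward flux at E_i = 0 is cancelled, and at the
budget face an outward derivative is projected onto the face's tangent
plane (re-checking the floor afterwards).  Projection was preferred over
soft penalties because it makes the feasibility guarantee exact and
testable; after each Euler step the state is additionally clipped and
multiplicatively rescaled to absorb curvature overshoot.  Multiplicative
rescaling (rather than clipping) is also the budget projection used
everywhere else, because it preserves enzyme ratios, i.e. nutrient
preferences.  Default timescale k_τ = 0.01: regulation responds faster than
a generation (~10 time units) but much slower than chemical relaxation.

The isolated replay (`protocrm replay`, and `integrate_enzymes`) advances
each Euler interval with the concentrations recorded at its right endpoint,
the same convention as the engine, so a replay against recorded forcing
reproduces engine enzyme dynamics to floating-point accuracy.

## Evolution

At each division the daughter mutates with probability 1/E_div (default
E_div = 100, i.e. a 1% speciation probability per division — unstated in the
source conditions; chosen once as a realistic rate that yields
trunk-substitution intervals of order 10³ time units, so lineage statistics
stabilize within desk-scale runs).  The mutation kernel perturbs each
parameter independently with probability p_mut = 0.3 by additive Gaussian
noise: σ = 0.05 on metabolic weights, σ = 0.1 on network weights, biases
and decay constants (clipped at zero), and σ = 1.0 enzyme units (~3% of the
midpoint) on the enzyme baseline.  The enzyme baseline must be evolvable:
without it the −REG condition would have no route to phylogenetic adaptation
of nutrient preferences.  Diet sets are inherited exactly (major
evolutionary innovations are structurally excluded).  A metabolic
perturbation that violates the thermodynamic rule is resampled (≤ 20 tries,
then the weights are left unchanged), so every child is valid by
construction.

Lineage analyses operationalize the phylogeny trunk: the trunk is the
root-to-leaf path ending at the extant type with the largest time-integrated
biomass over the final 10% of the run (ties: earliest birth; if everything
is extinct, the last type to die).  Significant variants are the non-root
trunk nodes with a trunk child.  The trunk-enzyme series reports, at each
sample, the enzymes of the youngest trunk type already born (children take
over at their birth), with unrecorded gaps flagged rather than interpolated.
Quasi-species richness counts types with at least one individual; the
first 20% of each run is discarded as burn-in.  A
`count_evolvable_parameters` diagnostic reports how many heritable
parameters the kernel touches (6 for the −REG case-study founder; 45 for
+REG); the counting convention is declared, not calibrated.

## Deterministic mode

LSODA (stiffness-switching, rtol 1e−8) on the packed (c, p, E) system; when
regulation is active the budget projection is applied at output times
(operator splitting).  Negative excursions are clipped to zero with a
warning — consistent because all Monod terms vanish at zero.  Steady states
are found by relaxation integration, dropping washed-out types (p < 1e−9),
Newton polishing (`scipy.optimize.root`), and a short stability
re-integration; an all-extinct attractor is reported as "none found" with an
extinction diagnosis rather than as the trivial equilibrium.

## Scenarios and study conditions

Feeds: constant at 200 concentration units per fed nutrient, or anti-phase
sine waves between 40 and 200 units (mid 120, amplitude 80, phases 0°/180°)
with period 2.5e6 (slow), 2.5e5 (medium) or 2.5e4 (fast) time units.  Case
1: one founder eating nutrients 0 and 1 (diagonal by-product weights 0.4,
Δv = 0.8).  Case 2: symmetric cross-feeding pair.  Case 3: cross-feeding
plus competition for nutrient 1; its initial weights are a representative
validated stand-in (the original values are not published in the text this
model works from) and can be overridden in the builder or the config file.

## Problem sizes used by the tests and the acceptance script

Desk-scale sizes were chosen so each statistic stabilizes: the constant-feed
case-1 run uses τ_end = 1.2e5 (≈ 60–80 significant variants, ≥ 50 as
required for the enzyme statistic); the fast-forcing regulation comparison
runs 10 seeds per condition to τ_end = 1.2e5 (≈ 5 forcing periods), scoring
the in-phase enzyme–feed Pearson correlation after τ = 4.5e4 and comparing
conditions with a one-sided Mann–Whitney U test; the deterministic-limit
check compares stationary time-averaged biomass against the ODE equilibrium
at b₀ ∈ {1, 0.5, 0.25} with 10 replicates each; the speciation-frequency
check accumulates > 1e5 divisions.  The acceptance script's evolutionary run
is seeded from its `--seed` argument; all tests use fixed seeds.

## What the synthetic scenarios do and do not show

All experiments are self-generated: the feed schedules, growth values and
founders above *are* the study conditions, not calibrated fits to data.
Passing tests therefore demonstrate internal consistency (stochastic ↔
deterministic agreement, constraint preservation, analytic limits) and the
qualitative evolutionary phenomena (symmetric allocation, quasi-species
clouds, regulation emerging under fast forcing) under these conditions.
They do not show robustness across the wider parameter space (E_div,
mutation widths, b₀), chemical realism of the value assignments, or any
claim about wet-lab protocells.  Known limitations: no cost is charged for
carrying a regulatory network, so +REG is never penalized for complexity;
the tau-leap step control trades some distributional accuracy for speed
(means are bias-corrected, higher moments are approximate); and case 3 is
sensitive to its stand-in initial weights.
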