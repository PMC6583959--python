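# Methods

`porecosm` simulates bacterial life in pseudo-two-dimensional angular pore
networks: a physical lattice of pores, a capillary description of the
aqueous phase at a prescribed matric potential, implicit solute diffusion
through the retained water, and individual motile agents whose growth and
exchange fluxes come from node-pooled dynamic flux balance analysis (dFBA).
This note records the model, its assumptions, the parameter choices that
were genuinely open, and what the synthetic scenarios do and do not show.

## Physical domain

Networks are lattices (square, coordination 4; hexagonal packing,
coordination 6) or disc clippings of them ("aggregate cross-sections").
Each pore is a straight channel of length L whose cross-section is an
isosceles triangle (inscribed-circle radius r, apex angle γ) or a rectangle
(W × H).  Triangle area is A_t = r² Σᵢ cot(αᵢ/2).  Pores carry a scalar
extrusion depth used only for volume/porosity bookkeeping; it never enters
diffusion or growth.

Pore radii are drawn from a lognormal parameterised by its *arithmetic*
mean and standard deviation.  The default apex angle is γ = 5°: soil pore
space is dominated by slit-like wedges between grain contacts, and an
acute apex reproduces the strong corner retention such pores show — a pore
of inscribed radius r then drains only once the meniscus radius σ/|Ψ|
approaches r (the drainage threshold is r* = f(γ)·σ/|Ψ| with f ranging
from 0.63 for an equilateral section to 0.95 at γ = 5°).  This single
angle cannot simultaneously make a 50 µm-radius network hold ≥99% of its
water at −1 kPa *and* let air percolate a 5 µm network at −10 kPa; we
resolve the tension in favour of the retention behaviour (see
Limitations).

Porosity is defined against a domain volume frozen at construction
(plan area × depth), which makes `rescale_length_for_porosity` exact,
idempotent, and consistent with comparing networks of different pore sizes
inside the same domain.

## Hydrological domain

At matric potential Ψ < 0 (stored negative; Ψ = 0 is saturation by
definition) every corner of angle γᵢ holds

    A_corner = (σ/Ψ)² · [cot(γᵢ/2) − (π/2 − γᵢ,rad/2)],

summed over corners and capped at A_t.  A pore with corner sum below A_t
actually drains only if a continuous path of such pores connects it to an
air interface at a declared boundary set; enclosed candidates are forced
saturated (trapped air is not modelled).  The film thickness that limits
motility is the *diameter* of the circle inscribed between wall and
meniscus, WFT = 2(σ/|Ψ|)(1 − sin(γᵢ/2))/(1 + sin(γᵢ/2)), taken per pore as
the minimum over corners; saturated pores carry no film restriction.  Both
formulas are dimensionally fixed (area ∝ (σ/Ψ)², length ∝ (σ/|Ψ|)) and
verified against independent numerical constructions of the meniscus
geometry in the test-suite.  Node water volumes are V_w = Σⱼ A_w,j L_j / 2
over incident pores.  The Millington–Quirk relative diffusivity is
reported as (θ/φ)^(10/3), i.e. normalised to its saturated value.

## Chemical domain

Between-node diffusion uses pore conductances g = A_w·D/L and backward
Euler, (I + dt·M)C⁺ = C with M the volume-scaled conductance Laplacian.
The scheme is unconditionally stable and conserves moles exactly in closed
systems; the sparse LU factorisation is cached while the hydration state
is unchanged.  Fixed-concentration boundaries are identity rows.
Oxygen-type solutes are additionally clamped at every node touching an
unsaturated pore: gaseous diffusivity is ~10⁴× aqueous, so the gas phase
is treated as equilibrated within one time step (Henry's law,
C = k_H·p; k_H = 1.3·10⁻³ mol L⁻¹ atm⁻¹ and p = 0.2095 atm give 0.27 mM).
Concentrations are mol m⁻³ internally (numerically mM).  Biological
consumption is subtracted from node contents *before* the diffusion solve.

## Biological domain

**Growth.**  Per step, agents are pooled by node and species; one FBA per
occupied (node, species) maximises biomass flux subject to S·v = 0 and
bounds.  Uptake bounds come from the local environment:
bound = min(max_uptake, moles_available/(B_gDW·dt)), which guarantees the
step never removes more than the node holds.  When several species share a
node, available moles are divided equally per cell with unclaimed surplus
redistributed (water-filling); because this allocation is pooled and
deterministic, no agent iteration order can bias contested resources, and
the engine therefore does not shuffle agents.  The node growth rate is
applied to every pooled agent as a net rate against the species
maintenance cost, m ← m(1 + (μ − r_m)·dt): cells growing slower than
maintenance shrink, which is what gives the system a genuine carrying
capacity (default r_m = 10⁻⁶ s⁻¹ ≈ 0.086 day⁻¹ for soil species —
starving soil bacteria persist for weeks).  Agents divide at a prescribed
mass into two equal daughters (no partition noise; intra-species variation
is deliberately absent) and are removed at a critical mass.  Super agents
represent a fixed number of identical cells; `mass` is always per-cell.

One subtlety of the availability bound: the dissolved inventory C·V_w per
step is the right cap for aqueous solutes, but at nodes in contact with
the gas phase it would throttle oxygen to far below the physical gas-phase
resupply (the artifact grows with dt).  Air-equilibrium solutes are
therefore bounded only by the kinetic max-uptake at their clamped nodes,
and any moles drawn beyond the dissolved inventory are booked in the mole
ledger as gas supply.

**Motility.**  Run-and-tumble within each step: a tumble (probability p_t)
flips the running direction with probability 1/2; at nodes the next pore
is drawn uniformly from all incident pores including the arrival pore;
leftover displacement is spent in the newly chosen pore, so speed is
independent of lattice discretisation.  The restricted velocity follows
the force balance V = V₀(F_m − F_λ − F_c)/F_m (zero when non-positive).
The film-to-force map is pluggable; the default uses
F_λ = a·exp(−WFT/λ_d) and a hard pinning cutoff (F_c = ∞) below a
threshold film thickness (at least the cell diameter; soil species default
to 10 µm, reflecting the observation that flagellated motility in
unsaturated media ceases at modest suctions, well before films reach cell
size) — the published force derivation is external to this package, so
these coefficients are structural placeholders, not canonical values.
An agent in a pinning pore escapes to the node it entered from with
probability 0.1 per step.  Chemotaxis rescales the tumbling probability,
p_t = p₀·exp(−X·Δμ/(2vμ_max)), with Δμ = (μ_t − μ_{t−1})/(v·dt) the
growth-rate change per distance travelled; p₀ is a per-step probability at
the configured dt (the two are coupled; halving dt without halving p₀
changes the effective tumbling rate).

**Update order.**  pool → dFBA → growth → chemistry → motility →
division/death.  Only "consumption before diffusion" is externally
constrained; the rest is this package's canonical order and is recorded in
run metadata.  All randomness flows from one seeded generator; a repeated
seed reproduces every output bit-for-bit.  Every step closes a mole
ledger per solute (Δstorage = boundary influx − consumption + production);
violations abort the run.

## Toy metabolic models

Curated genome-scale models (and their published reductions) are external
artifacts; the package ships small invented, carbon-balanced stand-ins
whose *route structure* carries the mechanisms the scenarios test:

* `toy_aerobe`: glucose + O₂ only; no acceptor → no growth.
* `toy_facultative`: one glucose pool feeding aerobic respiration (30 ATP),
  denitrification (12 ATP), and overflow fermentation (2 ATP, excreting
  acetate), plus aerobic acetate re-assimilation and a gluconeogenic route;
  the LP therefore prefers O₂, falls back to nitrate, and excretes acetate
  exactly when electron acceptors bind.
* `toy_pair`: obligate mutualists — a lactose consumer that needs
  methionine and overflows acetate under its microaerobic O₂ cap, and an
  acetate consumer whose methionine export is stoichiometrically coupled
  to biomass.  Neither grows alone.

Yields are scaled so optima sit at realistic 0.3–0.8 h⁻¹.  The glucose cap
is 8 mmol gDW⁻¹ h⁻¹ and oxygen 30 mmol gDW⁻¹ h⁻¹, the conventional
values.  All quantitative claims tested against these models are
mechanism-level (route switching, cross-feeding, overflow); none of the
published species-specific flux values are asserted.

Reduced-vs-full model consistency is assessed by flux variability
analysis over a grid of uptake fractions (100/60/20% of each substrate's
cap, full Cartesian product: 81 conditions for four substrates, 27 for
three), binning max(|Δmin|, |Δmax|) of each common reaction's envelope
into <0.1 / 0.1–1 / 1–10 / >10 mmol gDW⁻¹ h⁻¹.  Whether growth is fixed
at 100% of the optimum during FVA is configurable (`fraction`), defaulting
to 100%.

## Linear programming

FBA, FVA and dFBA solve against one persistent GLPK problem per model
(bounds mutated in place, warm-started simplex, ~4 µs per solve), which is
what makes one LP per occupied node per species per 10 s step tractable.
Simulations reset solver state at start so runs are reproducible
regardless of prior use of the model objects.  Exchange fluxes are clamped
to their bounds after the solve to keep availability accounting exact at
machine precision.  Degenerate optima: only μ and exchange fluxes that are
unique (verified by FVA in the fixtures) are treated as contract.

## Scenarios and their reduced scale

`scenario(name, scale)` emits complete configurations; `scale` multiplies
domain size and duration.  Desk-scale runs in the test-suite and the
acceptance script additionally coarsen dt (60–120 s instead of 10 s) and
thin inocula or raise super-agent ratios; the problem sizes actually used
are: cross-feeding on a 4×4-node saturated lattice, 48 h, dt 10 s;
segregation in a 2.5 mm disc (~140 nodes), 24 h, dt 60 s; glucose pulse on
the full 2 mm disc (~360 nodes), 9 days, dt 120 s; wet/dry contrast on
0.6–4 mm discs (90–810 nodes depending on pore class), 1.5–2.5 days,
dt 120 s.

Scenario-level modelling choices.  (0) Pore cross-sections: the
structured-soil wet/dry networks use the acute wedge default (γ = 5°),
while the aggregate of the glucose-pulse scenario uses near-equilateral
pores (γ = 60°, the granular pore-network convention) — there, air must
percolate the aggregate at −10 kPa for the interior to be oxic, which an
acute wedge geometry forbids at a 10 µm mean pore diameter.  The wet/dry
source concentrations are scaled per network by the inverse of the
centre-pore conductance scale A_t/L (constant-flux boundaries), and the
pulse event leaves the central source in place (biological consumption
outpaces diffusive loss to the clamp) so the pre-pulse carrying capacity
is restored after the bloom.  (1) The cross-feeding medium
carries a 0.02 mM unreplenished methionine trace: with strict FBA the
obligate pair cannot bootstrap (zero growth exchanges nothing), and the
trace stands in for the cellular reserves and leakage real cultures start
with; it is identical for both inoculation ratios.  (2) In the
segregation scenario the dispersal speed is V₀ = 1 µm/s with chemotactic
sensitivity 5·10⁻⁹ m² s⁻¹: dispersal in 15 µm-deep liquid chambers is
film- and surface-limited (mm/day, far below free swimming), and with
free-swimming speeds the scaled-down domain mixes completely every few
steps, erasing all spatial structure regardless of the biology.

## What the synthetic scenarios do and do not show

The generators emulate the *mechanisms* — obligate cross-feeding reaching
a composition set by stoichiometric coupling; aerobe/facultative
segregation along carbon–oxygen counter-gradients; a carbon pulse driving
a transient bloom that collapses back toward the carrying capacity;
hydration-controlled switching between aerobic and denitrifying growth.
They do not reproduce the published species-specific numbers, which
depend on curated genome-scale models, wet-lab inocula and multi-day
full-scale runs.  Passing tests therefore demonstrate that the physics,
the dFBA coupling and the emergent community behaviour are implemented
coherently, not that any particular soil isolate behaves as simulated.

## Numerical choices and degenerate inputs

Backward Euler is first-order; at dt = 10–120 s and the diffusivities used
(5·10⁻¹⁰ m² s⁻¹) splitting error is far below the biological variability.
Ψ = 0 bypasses all corner formulas (saturated by definition).  Isolated
zero-volume nodes make the implicit system singular and are rejected by
name.  Ties in node assignment (s = 0.5) go to the lower-indexed endpoint.
Division splits are exactly 50/50.  The movement loop caps node crossings
at 64 per step and truncates the residual beyond that (reached only if
V·dt spans tens of pores, far outside intended resolution).

## Known limitations

* Single corner angle per network: with γ = 5° the 5 µm network's interior
  stays saturated (hence anoxic) at −10 kPa because drainable pores do not
  percolate from the boundary; the wet/dry metabolic contrast is therefore
  carried by the 50 µm network, which is ~fully saturated wet and fully
  drained dry.  A network with heterogeneous corner angles could show the
  contrast in one network, at the cost of the clean retention ordering.
* No wetting/drainage hysteresis, adsorbed films, or contact angles ≠ 0;
  hydration is static within a run.
* Gas transport is an instantaneous clamp, not a second diffusion field.
* No agent–agent exclusion, attachment, or biofilm mechanics; overflow of
  an agent-count budget is handled by super-agent scaling, whose
  congruence with individual runs is itself a tested property.
* The film-to-force coefficients (a, λ_d, F_m) are structural defaults;
  quantitative motility restriction in real films requires the published
  force model they stand in for.
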