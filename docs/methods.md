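# Methods

## Model overview

`feedscape` simulates *N* point individuals with unit mass on a square
torus of side *L*, coupled to a pair of nutrient grids at 0.1-unit cell
resolution: *Q* (available to foragers) and *U* (an underlying reservoir).
Individuals are damped self-propelled particles; their only direct social
interaction is short-range repulsion.  All other coupling between
individuals is indirect, through the nutrient fields: individuals consume
from *Q*, and their movement frees nutrients from *U* into *Q* at a rate
proportional to their speed.  That disturbance term is the model's central
assumption; it creates a trail of locally elevated available nutrients
behind moving individuals, and the gradient-seeking force then feeds back
on movement.

## Update scheme and ordering

Each step (Δt, default 0.1 s) proceeds in a fixed order:

1. the nutrient fields advance one step using the current positions and
   velocities;
2. forces are computed for all individuals from the freshly updated fields;
3. all individuals move synchronously.

Motion uses semi-implicit Euler: `v' = v + Δt·F`, then `x' = wrap(x + Δt·v')`.
With drag −γv against a constant unit propulsion the scheme has the exact
fixed point |v| = 1/γ (≈ 0.833 for γ = 1.2), which the tests verify to
1e−6.  An explicit-Euler variant would change one line in
`forces.integrate_step`; semi-implicit was chosen for its stability with
damped self-propelled particles at Δt = 0.1 s.

Every run is a pure function of its configuration: a single
`numpy.random.Generator` seeded from `cfg.seed` supplies the initial
conditions and then one stochastic-force draw per individual per step, in
fixed order.

## Field dynamics and the clipping rule

Each named rate is applied per step as `amount = rate · Δt · stock`.  The
rates carry units of s⁻¹, so this is the forward-Euler discretisation of
the continuous exchange processes.  Diffusion uses the 4-neighbour von
Neumann Laplacian on the torus — the simplest conservative stencil — with
each cell sending `Δt·δ_diffuse·Q` to each neighbour.

The disturbance term transfers `Δt·δ_disturb·|v_j|·U` from *U* to *Q* at
each occupant's cell.  It is implemented as a transfer proportional to the
local underlying stock, not unbounded creation: disturbance *frees*
existing reservoir nutrients, and the matching loss term in the reservoir
equation requires the two fields to exchange the same amount.  A
consequence worth knowing: once the local reservoir is exhausted,
disturbance yields nothing, so swirling is self-limiting on long
timescales.

When a cell's combined outflows in one step exceed its stock (possible
only at extreme rate × Δt products), all outflow terms from that cell are
scaled by the common factor `stock / total_outflow`, so the available
quantity is distributed over the competing processes according to their
relative weighting and the cell lands exactly at zero.  Inflows are the
scaled outflows of the source cells, so the invariant
`sum(Q) + sum(U) + cumulative_consumed = initial total` holds to machine
precision (observed ≲ 1e−15 relative over 3000 steps; the test bound is
1e−9).

## Gradient sensing

The sensed gradient at cell (k, l) is the vectorial sum of
`[Q(m,o) − Q(k,l)] · q̂` over all cells of the square window of half-width
`w = round(R / 0.1)` cells (5 for the default R = 0.5), where `q̂` is the
unit vector between cell midpoints (minimal image).  The focal cell is
excluded (its direction is undefined and its difference is zero).  The
window is square, following the per-axis index-range definition of the
sensor.  The sum is normalised to a unit vector; if its norm is below
1e−12 — a locally homogeneous field, or exact cancellation — the food
gradient component f₁ is (0, 0).

## The propulsion term f₂

f₂ is a unit vector that keeps individuals from stalling.  With
s = v · f₁: along v when s > 0; when s < 0, the unit vector orthogonal to
v that minimises the angle to f₁ (the orthogonal on the sign side of the
cross product v × f₁), enforcing a turn toward nutrients rather than
braking and reversing.  Degenerate cases are fixed deterministically:
s = 0 with both vectors nonzero takes the orthogonal branch with the tie
broken toward positive cross product (which reduces to f₂ = f₁, since f₁
is then itself orthogonal to v); f₁ = 0 gives pure self-propulsion along
v; v = 0 gives f₂ = f₁.  The f₁ = 0 fallback is what produces the
near-linear ballistic motion of non-interacting individuals: drag and unit
self-propulsion balance at speed 1/γ, perturbed only by the stochastic
force.

## Repulsion magnitude

The avoidance force on i is one unit vector away from each neighbour
within r, i.e. direction-only with a Heaviside range gate.  The
parsimonious constant-magnitude reading was adopted because the
interaction is specified by range and repulsive character only; coincident
individuals (distance exactly 0, direction undefined) contribute nothing.
Distances everywhere — repulsion, grouping — are toroidal (minimal image),
for consistency with the periodic domain.

## Initial conditions

Positions are iid uniform on the box; initial speeds are exactly 1 with
iid uniform headings.  The underlying field starts either homogeneous
(`food_per_cell` = 10 units in every cell, total `10·(10L)²`) or patchy:
the same total placed as unit parcels around one uniformly chosen centre
cell, each parcel offset by two independent draws from a standard normal
(in cell units) rounded to integers, wrapped periodically.  *Q* always
starts at zero, so there is a short lag before background infusion makes
any nutrients available.

## Summary statistics

Computed per step and averaged over the trailing analysis window (default
last 50 s of a 300 s run, i.e. 500 steps):

- **Groups**: connected components of the strict `distance < r` graph
  (boundary equality is measure-zero; strictness makes the partition
  deterministic).  Largest-group ties break to the group containing the
  lowest agent index.
- **Polarisation**: length of the mean unit displacement vector of the
  largest group's members; zero displacements contribute zero vectors but
  stay in the denominator.
- **Angular momentum**: `|Σ r̂_jc × ŝ_j| / N_l` about the group centre.
  The centre on the torus is the per-axis circular mean (the arithmetic
  mean is ill-defined across the wrap).  Both need the largest group to
  have ≥ 2 members; steps failing that are excluded from the average, and
  a window with no valid step reports NaN — missing values are always
  explicit NaN, never 0.
- **Tortuosity**: arc-chord ratio over consecutive non-overlapping 2 s
  windows of the unwrapped path (accumulated minimal-image displacements),
  averaged across individuals and windows.  Windows with chord < 1e−9
  (closed loops) are dropped rather than capped, avoiding unbounded
  values.
- **Consumption**: mean food units per individual per step; the normalised
  variant divides by δ_deplete and is defined as exactly 0 when
  δ_deplete = 0.  A member-subset restriction supports largest-versus-
  smallest-group contrasts.

A population-level polarisation (all N individuals) is available as an
option and in the time-course tables.

## Experiment drivers

Per-run seeds are derived as `SeedSequence((master, combo_index, rep))`,
making every sweep embarrassingly repeatable and each run reproducible in
isolation.  The interaction sweep covers a `(δ_deplete, δ_disturb)` grid
of equally spaced values on [0, 1] including both endpoints; the full
design (15 × 15 × 100 replicates ≈ 22,500 runs) is available behind the
`--full` flag, with desk-scale defaults (5 × 5 × 10) otherwise.  The
infusion sweep uses the reference combinations (0, 0), (0.214, 0.5),
(1, 1); the density sweep uses (0, 0) and (1, 0.1) and reports the largest
group normalised by N.  The time-course driver averages the statistics in
consecutive bins (default 8 s) over the whole run; a trailing partial bin
is dropped.  Aggregated tables carry mean and sd per combination and are
exactly re-derivable from the per-run tables; sd is missing (NaN) at one
replicate.

## What the synthetic conditions do and do not show

All inputs are synthetic by construction — the model's study conditions
are homogeneous or single-patch reservoirs and random initial states, and
the experiments are parameter sweeps over interaction strength.  Passing
tests therefore demonstrate internal consistency (conservation,
determinism, oracle equivalence of sensor and grouping) and the
qualitative regime structure: disturbance raising tortuosity and angular
momentum (swirling), strong interaction reducing group count and raising
largest-group size, and consumption increasing with δ_disturb.  They say
nothing about real foraging systems beyond this qualitative
correspondence: there is no energetics, no saturation of intake (by
assumption consumption stays below saturation), no alignment or attraction
social forces, and a flat, isotropic environment.

Regime checks run at desk scale: 20 individuals, 100 s runs with the
trailing 50 s analysed, and 10–20 replicates per condition.  These
shortened runs show the same regime directions as single-seed 300 s spot
checks; slow processes — the gradual coarsening of groups over hundreds of
seconds, and reservoir exhaustion at high infusion — need the full 300 s
(or longer) runs, which the configuration supports directly.

## Numerical choices and degenerate inputs

- Coordinates are half-open `[0, L)`; the antipodal minimal-image tie
  resolves to −L/2.  Grid indices are 0-based.
- Cell assignment is `floor(x / 0.1)` with half-open cells; the float edge
  where a wrapped coordinate rounds to L is clipped to the last cell.
- Gradient-sum norms below 1e−12 count as zero (exact cancellation
  dominates in practice; homogeneous fields give exactly zero).
- Non-finite positions and forces are rejected rather than propagated.
- duration and analysis_window are configurable (defaults 300 s / 50 s) so
  tests and sweeps can run at reduced scale without touching the model.

## Known limitations

- The O(N²) pairwise repulsion and grouping are fine for N ≤ 500 (the
  explored range) but would need spatial hashing beyond ~10⁴ individuals.
- The forward-Euler field discretisation requires rate × Δt ≲ 1 for
  accuracy; the clipping rule guarantees positivity but not accuracy at
  extreme rates (by design it is rarely triggered at the standard rates).
- Tortuosity windows are non-overlapping; a sliding-window variant would
  smooth the estimate but was not needed for the regime contrasts.
- The heat-map interpolation sometimes used to render sweep results is
  cosmetic and deliberately out of scope; the raw per-combination tables
  are the product.
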