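# Methods

This note documents the model implemented by the package, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Model structure and assumptions

The simulation is a yearly-step cellular model on a rectangular grid
(row 0 = northernmost row; cells addressed `(row, col)`, 0-based). Cells
are land, water, or high mountain; only land cells simulate vegetation,
and fires can neither ignite nor spread on water, high mountains, or
bare ground. Each land cell carries a climax (potential natural) state —
dominant PFT, openness, NPP, and a maximal megafauna consumption
capacity — and a mutable current state bounded by it: openness never
falls below the climax openness, NPP never exceeds the climax NPP, and
the current PFT is always one of {climax PFT, herbs, bare ground}.

Each step applies four processes in a fixed order: climatic
regeneration, anthropogenic fire, natural fire, megafauna consumption.
Regeneration runs first and therefore acts on disturbances from
*previous* steps; a cell burned this year stays bare until next year's
regeneration begins to close it. This ordering also means later
processes can overwrite the attribution of earlier ones within a step —
the model records the *last* agent, so human impacts are a minimal
detectable influence, not a total one.

### Regeneration

Openness recovers at the constant rate
`(openness_at_disturbance − pnv_openness) / T` per step, floored at the
PNV openness, with `T` the climax PFT's recovery time (herbs 7,
broadleaf trees 30, needleleaf trees and shrubs 43 years). Every new
disturbance (fire or consumption) resets `openness_at_disturbance` to
the current openness, so the rate always reflects the newest
disturbance; this is the mechanism by which repeated disturbance delays
recovery. Succession is clock-driven: bare → herbs at disturbance age 7,
herbs → climax PFT at age `T` (a no-op when the climax is herbs).
Regrowth that brings openness within 10 points of PNV re-attributes the
cell's openness to climate; every succession-driven PFT change
re-attributes the PFT to climate.

Because `T` repeated floating-point subtractions of `amplitude/T` need
not land exactly on the PNV openness, the engine snaps openness to PNV
when the residual is below 1e−9 of the disturbance amplitude. This makes
the recovery schedule exact: after a single burn, openness returns to
PNV in exactly `T` steps.

NPP is set to 0 by a burn and regrows linearly at `pnv_npp / T` per
step on *every* land cell below its PNV NPP (not only cells flagged as
recovering) — the closed-system choice that prevents cells from being
stranded below their climax NPP after the openness clock completes.

### Fire

Natural ignition: `round(f/100 × n_land)` land cells are struck
uniformly per step (`f` = thunderstorm fraction, default 0.04 % from
modern decadal lightning observations for Europe; with 10⁴ land cells
that is 4 strikes per step). A struck non-bare cell ignites with
probability `min(1, Δt / FRI)` — the published model states that
ignition probability depends on time since the last fire and on the
PFT's fire return interval but not the functional form; the
linear-saturating form is the simplest monotone choice and is
configurable. The fuel clock starts at FRI ("fuel fully accumulated") so
undisturbed landscapes can ignite from step one.

The per-PFT FRI and spread-probability values used by the original
model derive from remote-sensing work that is not part of this package;
they are configuration inputs here, with synthetic defaults (FRI 20 /
50 / 100 / 200 steps and spread 0.3 / 0.2 / 0.2 / 0.1 for herbs /
shrubs / needleleaf / broadleaf) chosen only to order flammability
plausibly (grassland burns and carries fire more readily than closed
broadleaf forest).

All fires replace vegetation with bare ground: openness 100, NPP 0,
both attribution variables set to the fire's agent. Spread is recursive
over the Moore neighborhood with probability `spread_probability[pnv_pft]`
per neighbor; within one step each cell's ignition roll happens at most
once, and already-burned (bare) cells cannot reburn.

Anthropogenic fire: each campsite scans its full Chebyshev square every
step and burns all woody cells below the openness criterion (no per-step
quota; an optional cap is provided but defaults to unlimited — the
source model does not state a burning frequency). Campsites are placed
uniformly at random on admissible land (never on water, mountains, or
human-exclusion cells, the layer representing regions foragers did not
occupy); optional relocation moves a configured percentage of campsites
every `movement_frequency` steps. The calibration experiments fix
relocation off, matching the published experimental setup.

### Megafauna

Consumption per cell and step: `V_h = max_consumption × (1 − HP/100)`
(hunting pressure HP forced to 0 on human-exclusion cells),
`V_m = (O_i/100) × V_h`, `V_c = 100 × V_m / V_n` with `V_n` the current
NPP. `V_c` is clipped to [0, 100]: the formulas alone permit
`V_m > V_n` on degenerate inputs, which would drive NPP negative.
Openness increases *additively* by `V_c` points (capped at 100) — the
source text says only that V_c is "combined with" openness; the additive
reading treats V_c as percentage points of vegetation removed.
Cells at openness 100 are not consumed; cells with `V_n = 0` are
skipped (nothing to eat), not an error.

Megafauna change a cell's dominant PFT only by driving openness to 100
(the cell becomes bare, attributed to megafauna) — the only mechanism
consistent with PFT replacement requiring conversion to bare ground.
For openness attribution, megafauna must sustain a deviation of more
than 10 points from PNV openness over 10 consecutive steps without fire
acting on the cell; this mirrors the requirement that the low-intensity
herbivory signal be comparable to a fire- or climate-scale
transformation before it is credited.

## Comparison and calibration

A cell enters comparisons and fitness evaluation iff it is land, has a
target estimate, and either its PNV openness is ≤ the target openness or
its PNV PFT is woody (disturbance only opens vegetation; woody cells can
still be converted to bare/herbs). "Trees" in dominance statistics means
broadleaf ∪ needleleaf; shrubs count toward neither trees nor herbs.

Fitness is `|O_r − O_h|/100` or `|T_r − T_h|/100`, both in [0, 1], with
the simulated statistics averaged over the post-equilibrium recording
window (steps 451–1000 at production scale; the recording mode is a
time-mean rather than an end-state snapshot, which smooths fire-driven
fluctuation). Success is fitness ≤ 0.10.

The genetic algorithm is a standard real/integer-coded design:
tournament selection (size 2), uniform crossover (rate 0.8), per-gene
Gaussian mutation (σ = 10 % of the gene's range, rate 0.2), elitism of
one, clipping and integer rounding after variation, one simulation per
evaluation. The published study delegates optimization to an external
optimizer without printing its operators, so these internals are this
package's own (configurable) choices; population size 30 and 20
iterations are the published defaults. Subset semantics fix the process
switches — (1) megafauna, (2) + natural fires, (3) + humans — and
restrict the free genes to hunting pressure in subsets 1–2.

Mode analysis bins continuous parameters at 1/20 of their search range
(integer parameters use unit bins; the source does not state a binning),
reports all tied bins as modes, and selects, for each element of the
Cartesian set of per-parameter modes, the evaluated record minimizing
range-normalized Euclidean distance (ties broken by lower fitness) — the
distance metric behind "closely matched" is not stated in the source and
is this package's choice.

## Synthetic data

The generator produces spatially autocorrelated PFT mosaics by
thresholding Gaussian-smoothed white noise (rank-transformed to uniform)
at the cumulative PFT-mix quantiles, with water and mountains carved
from an independent smoothed field. Openness is drawn per PFT (defaults:
herbs 85 ± 8, shrubs 55 ± 10, broadleaf 20 ± 8, needleleaf 15 ± 6 %),
reproducing the open/closed contrast between herbaceous and forested
cells. NPP defaults to 3–5 × 10⁵ kg km⁻² yr⁻¹ (≈ 300–500 g m⁻² yr⁻¹,
temperate-forest scale) and maximal consumption to 4–12 × 10³
kg km⁻² yr⁻¹, so per-step consumption percentages are of order 1 % —
the magnitude regime the herbivory attribution rules are built around.

Two target constructions are provided: an *offset* target (PNV openness
plus a constant, herb-dominated above a threshold, on a random coverage
subset), which emulates the empirical situation of pollen
reconstructions being systematically more open than the climate
baseline; and a *simulated* target (the engine's own post-equilibrium
per-cell time-mean openness and modal PFT under known true parameters),
which supports parameter-recovery experiments where the truth is known
by construction.

What these generators do **not** emulate: real geography and coastlines,
the spatial clustering of pollen sites, temporally ordered time windows,
dataset-specific biases of pollen productivity estimates, or correlated
uncertainty between openness and PFT layers. Passing tests on synthetic
landscapes therefore demonstrate the *mechanics* of the engine and the
*identifiability* of parameters under the model's own assumptions — not
the fidelity of any particular empirical reconstruction.

## Problem sizes used by the test suite

The production configuration (continental grids, 1000 steps, population
30 × 20 iterations × 60 seeds) is far larger than what unit tests need.
The test suite exercises the same code paths at reduced scale, chosen
once as the smallest sizes at which each property is informative:
parameter recovery on a 50 × 50 landscape with 150-step simulations
recording after step 100 (target and candidates share the identical
window, so recovery is well-posed even where slow cells are still
approaching equilibrium), GA population 10 × 5 iterations × 5 seeds,
validated against a grid-search oracle over hunting pressure; the
subset-contrast experiment on a 30 × 30 forest-dominated landscape with
10 seeds per subset; the ignition-attempt statistic on a 100 × 100 grid.
The acceptance script runs the full 1000-step configuration for the
strike statistic (it is cheap) and single-cell runs for the recovery
schedules.

## Known limitations

* Fire is isotropic and memoryless beyond the fuel clock: no wind, no
  seasonality, no fuel-moisture dynamics.
* Herbivory is a capacity field, not populations: hunting pressure
  rescales consumption instantly and uniformly, with no demographic lag
  or spatial movement of animals.
* All fires are stand-replacing; partial burns and fire scars are not
  represented.
* The additive openness update for consumption and the linear-saturating
  ignition form are simple monotone choices where the source model's
  exact forms are unpublished; both are configurable and both choices
  propagate into calibrated parameter values.
* One simulation per fitness evaluation makes fitness itself stochastic
  in subsets with fire; elitism can therefore retain a lucky evaluation.
  Replicate averaging is available but off by default, matching the
  published single-run evaluations.
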