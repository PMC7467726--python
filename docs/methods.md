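# Methods

## Model

The simulator couples three pieces of state on a square lattice with
unit spacing and unit time step:

1. **cell blocks** — at most one per site, each with a binary metabolic
   state (dark = gluconeogenic producer, light = glycolytic consumer)
   and two continuous internal reserves, carbon C and nitrogen N;
2. **an extracellular trehalose field** — one non-negative scalar per
   site, fed by dark secretion, drained by light consumption, smoothed
   by diffusion;
3. **implicit aspartate** — treated as spatially uniform and
   non-limiting, so uptake always succeeds and no aspartate field is
   tracked.

The model is deliberately coarse: a block stands for a small group of
cells, there is no death, starvation or reserve decay, and block count
is non-decreasing. Growth is Eden-like — division requires an empty
4-neighbor site, so the interior jams and expansion happens at the rim.

### Per-step algorithm

Each step processes every block existing at the start of the step
exactly once, in a fresh uniform-random permutation, then diffuses the
field once. Per block, in order:

1. **Switching.** A dark block at local trehalose u switches to light
   iff `u > T_DL` and an independent uniform draw falls below `P_DL`;
   a light block switches to dark iff `u < T_LD` with probability
   `P_LD`. A block that switches does nothing else that step; its
   reserves carry over unchanged (discarding them would introduce an
   unstated loss term).
2. **Metabolism.** Dark: `N += f·AspU·Cmax`;
   `C_tmp = C + (1−f)·AspU·Cmax·Y`;
   `secreted = min(Pf·C_tmp, secretion_cap)` added to the field at the
   block's site and deducted from the pool (deduction conserves carbon;
   the yield `Y` applies only to the carbon branch — the nitrogen
   allocation is the raw aspartate fraction). Light:
   `consumed = min(u, Cmax)` moves from the site to the C pool and
   `N += AspU·Cmax`.
3. **Division.** Reserve check (dark: `C ≥ 1` and `N ≥ 1`; light:
   `C ≥ 1` and `N ≥ ExN` — both comparisons uniformly `≥`, the boundary
   having measure zero for continuous pools), then a `g` draw, then
   site choice: among empty in-bounds 4-neighbors, the one with the
   most occupied 4-neighbors, ties broken uniformly. The mother stays
   put; the daughter takes the chosen site; each gets half the mother's
   pre-division pools and the mother's state. Daughters are inserted
   immediately but not processed until the next step, so no within-step
   division chains can occur.

The alternative reading of the light reserve rule, with the `ExN`
multiplier on carbon instead of nitrogen, is selectable via the config
key `light_rule: exn_on_c` for sensitivity checks; the default
`exn_on_n` follows the parameter's definition as extra nitrogen demand
of light cells (their higher nucleotide-synthesis rate).

A frequently asked ordering question — whether agents should see a
frozen start-of-step field or the live field — is vacuous here: every
block reads and writes the field only at its own site, and each site
hosts at most one block, so the two schemes produce identical
trajectories. Only one (live) code path exists.

### Diffusion

Forward-time centered-space (FTCS) explicit stepping:
`u' = u + D_eff·(u_N + u_S + u_E + u_W − 4u)` with `Δt = Δx = 1`, run
exactly once per step after the agent sweep. Stability requires
`D_eff ≤ 0.25`; this is enforced at config validation and again before
any stencil application, and within that region the update is a convex
combination of neighbor values, so non-negativity is preserved. The
boundary condition defaults to `no_flux` (edge replication — an agar
plate neither feeds nor drains trehalose at its rim), which conserves
the discrete field sum to rounding error; `absorbing` (zero padding) is
available and leaks mass at the rim. The boundary handling is an
assumption of this implementation, not a constraint inherited from
elsewhere.

## Parameters

| name | default | meaning (units) |
|---|---|---|
| `f` | 0.125 | dark aspartate flux fraction routed to N (–) |
| `AspU` | 4.0 | aspartate uptake relative to `Cmax` (–) |
| `Y` | 0.31 | aspartate-carbon → internal C yield (–) |
| `Pf` | 0.049 | C-pool fraction secreted per step (1/step) |
| `secretion_cap` | 0.12 | absolute secretion limit (trehalose/step) |
| `ExN` | 4.0 | light N-reserve multiplier (–) |
| `g` | 0.04 | division probability once reserves suffice (1/step) |
| `Cmax` | 0.05 | max trehalose consumed by a light block (units/step) |
| `T_DL`, `P_DL` | 1.5, 0.5 | dark→light threshold (units) and probability |
| `T_LD`, `P_LD` | 1e-4, 1e-4 | light→dark threshold and probability |
| `D_eff` | 0.24 | scaled diffusion constant (grid²/step) |

`AspU·Cmax = 0.2` is the per-step aspartate uptake of both cell types.
Useful closed forms for intuition: an undisturbed dark block's carbon
pool obeys `C ← (C + (1−f)·AspU·Cmax·Y)(1−Pf)`, a contraction with
fixed point `C* = (1−Pf)/Pf · (1−f)·AspU·Cmax·Y`. At defaults
`C* ≈ 1.053`, barely above the division threshold — dark division is
slow (first division no earlier than step 20, typically near step 60
from empty pools). At `f = 0.5`, `C* ≈ 0.60 < 1`, so dark blocks never
divide at all; at `f = 1` no carbon ever enters the system and the
colony freezes. These regime boundaries, not fine-tuning, drive the
parameter-sweep behavior.

Runtime settings: 201×201 grid (odd, centered; leaves ample head-room
around the radius-20 seed for 750 steps of growth), `n_steps = 750`,
`init_radius = 20` (closed Euclidean disk on integer coordinates,
giving 1257 sites), `init_dark_fraction = 0.97` (each initial block
independently dark with this probability — the midpoint of the stated
95–99% seeding range, with uniform placement of the light minority),
initial pools `C = N = 0` (forcing an accumulation phase before the
first divisions), empty initial field.

## Randomness and reproducibility

One `numpy` Generator seeded from the config drives everything:
initial state assignment, the per-step agent permutation, switching
draws (consumed only when the threshold condition holds), division
draws (consumed only when reserves suffice) and tie-breaks in site
selection. With the draw order fixed by this documented sub-step
order, identical (config, seed) pairs give bit-identical trajectories
and snapshots; snapshot files round-trip at 17 significant digits.

## What the simulations show — and what they do not

All inputs are self-generated; the package consumes no biological data.
A passing suite demonstrates the internal claims of the model: the
cross-feeding loop with these defaults self-organizes a light-enriched
rim over a persisting dark band, colony size increases with `AspU`,
and the `f` regimes above hold. It does not validate the model against
colony imaging, metabolite assays or any other measurement, nor fit
parameters to data — the parameter values are fixed inputs chosen for
pattern plausibility, and real colonies have continuous metabolic
states, cell death and nutrient depletion that the model omits.

## Numerical and testing choices

* Pools and field are float64 throughout; no clipping is ever applied —
  non-negativity holds structurally (secretion and consumption are
  bounded by what is available) and is asserted in tests rather than
  enforced.
* The per-block update is checked bit-for-bit against a straight-line
  reference implementation on 10⁴ randomized inputs with twin RNG
  streams; disk initialization counts are checked against a brute-force
  lattice enumerator.
* Stochastic regime claims (AspU-size ordering, rim enrichment) are
  tested as orderings of means over ≥ 5 shared seeds, not per-seed.
* Sweep tests and examples use 300-step runs on the default grid;
  full-length 750-step runs back the rim-enrichment and `f = 1`
  closure checks. Problem sizes in unit tests are smaller (grids
  41–101, radii 3–10) chosen so each test exercises the property at the
  smallest size where it is non-trivial.
* Colony "size" in sweep summaries is total block count, the lattice
  measure of the colony area panels; "radius" is the maximum block
  distance from the grid center.
* The secretion cap is diagnostic only at defaults: the run-averaged
  fraction of dark blocks at the cap is ~5·10⁻⁴, operationally
  "negligible" (< 5%).
* Reaching the outermost grid ring emits a warning (or aborts, if
  requested) because no-flux boundaries would then distort growth;
  default runs stay well clear (final radius ≈ 36 of 100 available).

## Known limitations

* The 4-neighborhood and synchronous-within-sweep field updates are the
  only supported topology/scheduling; no hexagonal, 8-neighbor or
  continuous-space variants.
* No trehalose degradation, aspartate depletion, cell death or pool
  leakage; long runs therefore accumulate extracellular trehalose
  without bound.
* FTCS is explicit and first-order in time; `D_eff` near 0.25 is stable
  but maximally dispersive. No implicit or ADI solver is provided.
* Division-interval statistics pool all divisions per state; they are
  not lineage-resolved beyond mother bookkeeping.
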