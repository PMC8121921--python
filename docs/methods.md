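# Methods

`mpaconnect` is a biophysical individual-based model of reef-fish egg and
larval dispersal between marine protected areas (MPAs), coupled to
thermal-tolerance mortality and demographic-connectivity statistics.  This
note documents the model, its assumptions, the tunable parameters, the
synthetic ocean generator, and the numerical and design choices.

## The biophysical model

### Transport

Particles (eggs, then larvae) are passive drifters in a gridded ocean state
`(u, v, T)(t, z, lat, lon)`.  Positions advance with the classical 4th-order
Runge–Kutta scheme at a **1 h step** (default), sampling velocity by
bilinear interpolation in lon/lat and linear interpolation in time.
Velocities in m s⁻¹ are converted to degrees with the local equirectangular
metric, 1° lat = 111.32 km and 1° lon = 111.32·cos(lat) km, evaluated at
each RK4 stage position.  At a 1 h step and sub-m s⁻¹ speeds the metric
approximation error is negligible relative to the field uncertainty.
Along-track distance accumulates as the haversine length (R = 6371 km) of
each hourly step, so cumulative distance is always ≥ net displacement.

Advection is horizontal.  The default `surface_layer` mode samples the
uppermost depth level; `fixed_depth` picks the nearest stored level and
`layered` interpolates linearly between levels.  No active buoyancy
dynamics are simulated: the literature value carried for egg specific
gravity (0.0089 g cm⁻³) is not interpretable as a seawater-relative
density, so it is retained as metadata only and eggs are treated as
surface-trapped, consistent with spawning "in the first metres of the
water column" (release depth uniform on 0–5 m).

### Life cycle and fates

* **egg phase**: 24 h from spawning, then the particle is a larva;
* **pelagic larval duration (PLD)**: 60 days, the genus-average drift time,
  after which a surviving larva is competent to settle;
* **fates** (exhaustive, exclusive, permanent): `alive`,
  `dead_hypothermia`, `dead_hyperthermia`, `advected_out`.

Step order is *advect → out-of-domain check → temperature check*.  Leaving
the domain and lethal temperature are separate fates; out-of-domain takes
precedence in the same step because temperature is undefined outside the
grid.  Death is immediate and permanent (no sublethal dose model), and a
dead particle's position and distance freeze.  A step that would land on a
masked land cell is reverted (no-slip beaching) and the particle stays
alive — the source observations are silent on coastline handling, and this
choice avoids spurious thermal deaths on land.

### Thermal tolerance

Survival requires the sampled temperature to lie inside the tolerance
window, bounds inclusive:

* **non-acclimated** (present-day tolerance): 24–30 °C;
* **acclimated** (transgenerational acclimation): 24–33 °C — acclimation
  raises only the upper lethal bound, by +3 °C.

Whether the original experiments treated the bounds inclusively is
unstated; "between 24 and 30 °C" is read inclusively here and the choice
only matters on a measure-zero set of temperatures.  The same window
applies to eggs and larvae (no stage-specific tolerance is reported).

Because trajectories are deterministic given the field and release, and a
particle's path is unaffected by other particles, any particle alive under
the narrow window is alive — with an identical trajectory — under the wide
window ([24, 33] ⊇ [24, 30]).  Per-site acclimated survival therefore
dominates non-acclimated survival exactly, which is the mechanism behind
the acclimation effect; the test suite asserts this run-for-run, along with
the sharper invariance that warming every cell by +3 °C while raising
t_max by +3 °C reproduces baseline fates particle-for-particle.

### Connectivity statistics

With `c_ij` the particles spawned at site *i* that are **alive at the final
timestep and located inside site *j***, `N_i` eggs spawned at *i*, and
`N_s` total eggs spawned at all sites, pooled over simulations *t*:

* recruitment rate `R_i = (Σ_t Σ_j c_ij) / Σ_t N_s` — note the
  denominator is the *network-wide* spawn count, so `Σ_i R_i` is bounded by
  the network's surviving-recruited fraction; this follows the printed
  formula of the rate it implements rather than a per-site normalization;
* local retention `LR_i = Σ_t c_ii / Σ_t N_i`;
* transition probability matrix `P[i, j] = Σ_t c_ij / Σ_t N_i`
  (source-normalized, so the diagonal reproduces `LR` exactly).

TPMs pool counts over years before normalizing (rather than averaging
yearly matrices); per-run records are kept in the experiment bundle so the
per-year variant can be recomputed.  A survivor outside every footprint
recruits nowhere (alive but not recruited), so
`row sum + (dead_i + unrecruited_i)/N_i = 1` exactly.

Density maps histogram every logged position of particles *while alive*
onto the grid, normalize within each simulation, pool simulations with
weight proportional to their living-particle count at the end (so
low-survivorship runs do not inflate the map), smooth with a Gaussian
kernel, and renormalize to unit mass over water.  Kernel and bandwidth are
not prescribed by the source analysis; the default bandwidth is one
grid-cell width and both are configurable.

Scenario contrasts use the tie-corrected **Kruskal–Wallis** H test over
per-site-per-year-season total mortality percentages (`scipy.stats.kruskal`;
the all-identical degenerate case returns H = 0, p = 1 rather than NaN).
Field-evaluation helpers `rmse` and `bias` implement the plain formulas
`sqrt(mean((x_model − x_ref)²))` and `mean(x_model − x_ref)` for any paired
sequences.

## The MPA registry

The packaged registry holds the nine federal reef MPAs of the southwestern
tropical Atlantic (SPSP, ML, FN, AR, RC, CC, AB, TR, CF) with their
published areas (km²), centroids and per-event reference release counts.
The original site geometry (ocean-model grid cells) is not published, so
synthetic footprints default to area-matched squares centred on the
centroids; arbitrary polygons can be supplied via a `wkt` CSV column.
Containment is boundary-inclusive and footprints must be pairwise disjoint.

Release budgets are distributed **proportionally to area** with
largest-remainder rounding (ties to the larger area), which conserves the
total exactly — 70,000 eggs per season-year experiment by default.  The
published per-event counts (213, 530, … 692) are *not* proportional to the
published areas and do not sum to 70,000; the schedule relating them to the
seasonal total is unstated, so the package exposes both the proportional
mode and an explicit `per_site_counts` mode and does not guess the original
schedule.  The default schedule places one release event at the start of
each month of a two-month season (2 events/season-year), splitting the
budget equally.

## The synthetic ocean generator

The generator replaces a regional eddy-resolving downscaling with idealized
fields that preserve what the transport-mortality chain actually consumes:
smooth currents, a meridional SST structure, seasonal warming offsets, and
seeded variability.

* **Grid**: regular rectilinear lon/lat (not the curvilinear sigma grid of
  ocean models), fixed z-levels, hourly-to-3-hourly time axis; the demo box
  spans 10° N–30° S, 70° W–20° W at a configurable resolution.
* **Currents** (analytic presets): `uniform`; `solid_body_rotation`, whose
  velocity is chosen so the trajectory ODE in degree space is exactly
  circular and whose planar divergence vanishes identically — the
  integrator's convergence oracle; `zonal_jet`, a Gaussian jet truncated to
  exactly zero beyond four widths; `coastal_shelf_system`, a southward
  western-boundary jet with a weaker inshore shelf flow.
* **SST**: constant, linear, or tanh meridional profile.  The demo pattern
  `26 + 2.6·tanh((lat + 14)/4)` °C gives a ~28.6 °C tropical pool cooling
  to ~23.4 °C at 30° S (below the 24 °C lower lethal bound, so the
  historical state contains hypothermic water).
* **Scenario offsets**: the future state adds **+3 °C in summer and +4 °C
  in winter** — the end-of-century warming signal at the protected sites
  under an extreme emissions trajectory.  Under these offsets the six
  tropical sites (SPSP, ML, FN, AR, RC, CC) sit above the 30 °C
  non-acclimated maximum while the three southern sites (AB, TR, CF)
  remain inside the window — the geography that produces the tropical
  die-offs and their rescue by acclimation.
* **Variability**: smooth (Gaussian-filtered, σ = 3 cells) seeded noise,
  0.05 m s⁻¹ on currents and 0.2 °C on SST in the demo scenario, standing
  in for interannual variability across year-replicates; fields are
  bit-identical under identical spec + seed.

What the generator does **not** emulate: mesoscale eddies, vertical shear,
tides, coastally trapped waves, land geometry beyond an optional
rectangular coast strip, and any air–sea physics.  Passing tests therefore
demonstrate the correctness of the transport/mortality/connectivity
machinery under controlled conditions, not the realism of any particular
regional ocean state; real-ocean connectivity values require real
downscaled fields, which are outside this package's scope.

## Experiment orchestration and reproducibility

`run_experiment` iterates seasons × years × windows.  Per (season, year) a
field is generated with a seed derived from the master seed, and release
positions are drawn once — both **independent of the tolerance window**, so
window comparisons are paired particle-for-particle.  All derived seeds
come from `numpy` `SeedSequence` over (master, context…) and stay below
2³¹.  Field time coverage is validated against the release schedule + PLD
before any simulation starts.  Outputs (fate tallies, TPMs, LR/R tables,
distance summaries, density maps, Kruskal–Wallis table, provenance JSON
with a config hash) are byte-stable under a fixed config and seed.

## Problem sizes

The default demo configurations run at desk scale: 0.5° fields with
3-hourly snapshots, 6,000 eggs per season-year, eight year-replicates, a
60-day PLD at a 1 h step for the reproduction script; the test suite uses
1° fields, 1,200 eggs and a 12-day PLD.  These sizes were chosen so the
full matrix (32 simulations) completes in minutes on one core while keeping
every per-site contrast far from its decision boundary; all statistics are
size-parameterized and scale to the full 70,000-egg budget unchanged.

## Known limitations

* No larval behaviour (swimming, orientation, vertical migration), no
  turbulent diffusion, no temperature-dependent PLD or growth.
* Recruitment competence only at the final timestep; no settlement window.
* The Kruskal–Wallis replicates pool sites within a window group, treating
  per-site mortalities as exchangeable replicates.
* Whether published travel distances are along-track or net displacement is
  unstated; along-track is implemented (net displacement is recoverable
  from the endpoints kept in every trajectory set).
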