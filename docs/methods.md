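# Methods

## Model

The unit of analysis is a grid cell (default 1 km² = 100 ha) that is either
native vegetation (1) or under anthropogenic use (0), observed at two-year
intervals.  Conversion is one-way: the model describes loss only, with no
regeneration.  The per-step conversion probability of a native cell is
logistic in a linear predictor over driver covariates,
`P = 1/(1 + exp(−k))`, `k = β₀ + Σ β_v z_v`.  All spatial dependence is
carried by the covariates; conditional on them, cells convert
independently.  There are no spatial random effects.

### Covariates

Ten driver rasters plus one endogenous channel:

| variable | kind | standardized |
|---|---|---|
| land_cover (neighborhood anthropogenic fraction) | endogenous, recomputed every step | no (already in [0, 1]) |
| distance_to_roads / cities / rivers | static, distance transform | yes |
| dry_season_length, elevation, agricultural_potential | static fields | yes |
| cattle, permanent_agriculture, annual_crop_agriculture | dynamic, one layer per calibration period | yes (pooled across periods) |
| protected_areas | static 0/1 indicator | no |

The `land_cover` covariate is the anthropogenic fraction of the
(2r+1)×(2r+1) Moore window (default radius 3), edge-truncated, focal cell
excluded.  It is the only covariate that updates during simulation, so
local vegetation suppression feeds back into subsequent conversion — this
is the mechanism by which the model "updates" over time.  Defining the
neighborhood this way, and the radius, are package choices: the quantity is
under-determined by its reporting convention, and the window oracle tests
pin the implementation, not the ecology.

Continuous drivers are z-standardized over the calibration cells and the
(mean, sd) pairs are frozen; every projection step reuses them verbatim.
The protected-area indicator stays raw so its coefficient is directly
readable as a log-odds penalty for conversion inside protection.  Dynamic
drivers beyond the last observed period are held at their final layer; the
model deliberately does not forecast its own covariates.

### Calibration

Each period contributes one Bernoulli record per start-native cell
(a reversion anthropogenic→native in the inputs is a hard data error).
Likelihood is the ordinary logistic-regression likelihood with
probabilities clipped to [1e−12, 1−1e−12].  Priors are independent
N(0, 10²) — effectively flat at the achievable sample sizes but proper, so
the no-data limit is well defined (the chain then explores the prior).

Sampling is random-walk Metropolis.  The proposal is shaped by a Laplace
approximation at the posterior mode (Newton/IRLS with the prior as ridge),
scaled 2.38/√p, with the global scale adapted during burn-in toward a
20–40% acceptance rate; an isotropic proposal of fixed standard deviation
is available as an override.  Defaults: 6 000 iterations, 2 000 burn-in,
thinning to ≥ 1 000 retained draws (≥ 100 draws are required, one per
projection iteration).  Chains are checked with a Geweke-style
mean-stationarity score using batch-means variances (a naive iid variance
estimate falsely flags autocorrelated but stationary chains).

### Model selection

Candidates are scored by held-out log-likelihood at the posterior mean
(ties toward the smaller subset, then lexicographic).  The candidate list
is the greedy forward path over the ten drivers, with `land_cover` always
included; the path is built with cheap MAP fits and the definitive
comparison uses MCMC.  The default split is a seeded random 70/30 cell
split.

One property of this scoring is worth stating because it shaped the test
design: for a truly irrelevant extra variable, the expected held-out
penalty is ≈ r/2 nats against noise of ≈ √r, where r is the
held-out/training size ratio — independent of the sample size.  The
selection-consistency experiment therefore holds out the larger share
(85%) of records, where the true subset wins against a noise-augmented
subset in the clear majority of replicates; at 70/30 the comparison is
near a coin flip for a single spurious variable.  Selection is for
predictive parsimony, not significance testing; no multiplicity correction
is applied and medians, not p-values, are reported.

### Projection

One posterior draw per iteration (each iteration is an internally
consistent world), two-year steps to the horizon, 100 iterations by
default.  Constraints:

- **Protected areas** are a covariate during calibration (soft effect) and
  additionally a hard mask during projection; both behaviours are
  independently switchable (`pa_hard`).
- **Legal Reserve floors**: a property whose native cell count is at
  ⌈f · cells⌉ (f = LR fraction plus any scenario addition; the ceiling is
  computed with a 1e−9 guard so 0.2 × 10 floors at 2 cells) is frozen.  A
  within-step overshoot is cancelled in randomized cell order, so the floor
  is exact in every iteration — audited, not approximated.
- **Public land** (cells in no property, outside protection) converts with
  no floor, logged once.

Accumulated probability by year Y = (iterations converted by Y)/n — exact
on the m/100 lattice for a single model.  Ensembling averages probability
maps cellwise and pools the iteration ledgers.  The reported ± is the
half-width of the central 95% range of total loss across iterations; it
mixes posterior parameter uncertainty with binomial simulation noise, and
parameter uncertainty dominates at realistic sizes.

### Scenarios

Scenario = constraint transformation: LR overrides by region (never
decreasing), added protected cells, and a large-property rule freezing a
fraction of every property above an area threshold.  The rule is
**additive** to the LR by default (30% on a 20%-LR property freezes 50%),
with a `max(LR, rule)` mode available since the headline phrasing alone is
ambiguous.  Frozen cells are pinned to the currently native cells with the
highest native-neighborhood fraction (largest intact remnants), ties broken
at random.  Avoided loss can be computed by re-simulation under the
scenario constraints with paired per-iteration seeds (default) or by
statically masking the BAU probability map (`mask` mode, cheaper and more
conservative).

Paired seeding draws the per-step random fields unconditionally on the full
grid, so a BAU/scenario pair stays synchronized.  While no LR floor binds,
the scenario's converted set is then a cellwise subset of BAU's; once
floors start cancelling conversions the two runs may keep different cells,
and dominance is guaranteed in per-property counts rather than cellwise.
Both regimes are tested.

## Synthetic landscapes

The generator emulates the statistical structure of the real inputs, which
are not redistributable:

- **Drivers**: Euclidean distance transforms from randomly seeded source
  cells (roads/cities/rivers); Gaussian-filtered white noise (σ = 5 cells)
  for climate/terrain/economic fields; dynamic drivers drift between
  periods as AR(1) anomalies (ρ = 0.9); protected areas are smooth-field
  exceedances covering ≈ `pa_fraction` (default 10%) as contiguous blobs.
- **Properties**: target areas from a lognormal law (default median 300 ha,
  log-sd 1.5 — heavy-tailed, realizing all five classes C1–C5 on the
  default 200×200 grid), grown as contiguous regions from random seeds
  until the non-protected grid is exactly partitioned.  Regions are
  horizontal bands carrying LR fractions from the legal set
  {0.20, 0.35, 0.50, 0.80} (defaults: a 20% band and a 35% band).
- **History**: starting from an all-native landscape, each of the
  (default 4) periods applies the model's own logistic rule with known
  coefficients — intercept −3.3 and β = (distance_to_roads −0.6,
  agricultural_potential +0.5, protected_areas −1.3, land_cover +2.5) —
  giving ≈ 4–5% conversion per period.  The compact truth is a parsimony
  choice: it spans a distance driver, a smooth field, the binary indicator
  and the endogenous feedback, which is what recovery needs to exercise;
  the signs follow the calibrated pattern of frontier landscapes.  No LR or
  PA hard constraint is applied during generation: the observed record is
  taken as-is, and legal floors bind only in projection.

What the generator does **not** emulate: real geography and road/river
network topology, the spatial co-location patterns of census drivers,
property-boundary geometry from a cadastre, observation error in the
land-cover maps, or temporally varying conversion regimes (the generating
coefficients are constant across periods).  Passing tests therefore
demonstrate the machinery — identifiability, constraint enforcement,
arithmetic — under the model's own assumptions, not predictive skill on
real landscapes.

## Verification design

- Ground truth recovery: pooled per-period transitions on 200×200
  landscapes (~1.5×10⁵ records) refit with the generator's frozen
  standardization; each generating coefficient must sit inside its central
  95% credible interval in ≥ 18 of 20 seeded replicates, and mean bias is
  ≈ 10⁻² in standardized units.  Interval endpoints are estimated from all
  post-burn-in draws (no thinning): discarding draws only adds Monte Carlo
  noise to the quantiles.
- Exhaustive oracles: the AUC equals brute-force pair counting; the
  neighborhood channel equals a double-loop window count; a one-property,
  3-cell projection (with feedback and the exact floor, uniform
  cancellation) matches full absorbing-chain enumeration within three
  Monte Carlo standard errors at 10⁴ iterations.
- Constraint audits over a full 2016→2070 projection (27 steps × 100
  iterations): zero LR-floor violations, exactly zero accumulated
  probability on protected cells.
- Structure: probability monotone in the horizon, ensemble of identical
  runs is the identity, class/region ledgers conserve the total, manifest
  replay is byte-identical.

## Problem sizes and defaults used in the shipped experiments

Recovery uses the 200×200 default grid; the acceptance script's pipeline
runs on 120×120 with 2 500-iteration chains per candidate subset, 100
projection iterations, horizon 2070.  These sizes were chosen so that each
experiment's statistical target (coverage, selection consistency, audit
exhaustiveness) is met with comfortable power on a single CPU.

## Known limitations

- Dynamic drivers are frozen at their last observed layer during
  projection, so long-horizon loss attributable to *changes* in those
  drivers is not captured.
- The ± interval convention (central 95% across iterations) conflates
  parameter and simulation uncertainty; a variance decomposition is not
  provided.
- LR compensation between properties, vegetation recovery obligations, and
  any economic behaviour (land prices, commodity shocks) are out of scope.
- At the default 100-ha cell, properties of very few cells are coarsely
  constrained: a one-cell property's LR floor (⌈0.2 × 1⌉ = 1) freezes it
  entirely, so class-C1 loss is structurally near zero on coarse grids —
  consistent with loss concentrating in large properties, but partly a
  resolution artifact.
- The contribution table reports median posterior coefficients (zeros for
  variables excluded by selection); with unstandardized indicator
  covariates the magnitudes are log-odds and are not comparable across
  differently scaled covariates.
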