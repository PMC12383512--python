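# Methods

## The modelling problem

Two commercially fished pelagic species occupy overlapping grounds in the
Northwest Pacific (the study window is 34–45° N, 144–163° E, June–November).
Their distributions respond to the same ocean fields, but they also interact
— through shared prey and size-structured predation — so part of each
species' realized distribution tracks the *other species*, not the
environment. A model built only on abiotic covariates misattributes that
part or misses it. The package implements the standard two-stage remedy:
fit each species alone, predict its suitability everywhere, then hand that
predicted field to the other species' model as one additional ("biotic")
covariate and measure what it buys.

## Data model

- **Grid**: regular lat/lon lattice (default 0.25°, 44×76 cells), cells
  half-open `[low, high)` with the north/east domain edge closed, 0-based
  (i, j) from the south-west corner. Exported tables always carry
  cell-center coordinates as well.
  One published description of the window gives 144° E as the western edge
  and another 145° E; the grid takes 144° E by default and the bound is
  configurable.
- **Environment stack**: 13 monthly covariates per cell — temperature at
  0/50/100/150/200 m (°C), SSH (m), SSS, Chl-a (mg m⁻³), current components
  U and V (m s⁻¹), EKE, and two basin-scale monthly scalars (SSTA, ONI)
  broadcast over the grid. EKE is defined as ½(u′² + v′²) with anomalies
  taken against the month's spatial mean (the quantity is standard; this
  specific anomaly convention is the package's choice and is pinned by a
  test). Whether the two broadcast scalars belong in the fitted model is
  genuinely open; they are included by default and removable via the
  covariate list.
- **Cell samples**: one row per (species, cell, month, year) with summed
  catch/effort/hauls, CPUE as the ratio of sums (never a mean of
  per-record ratios), the covariate vector, and a completeness flag. Rows
  on masked cells stay in the table — sample counts must remain honest —
  but are excluded from fitting.

## Training target

The regression target is an empirical habitat-suitability index: CPUE
(tons per fishing day) min–max normalized to [0, 1] within each
(species, month) stratum, pooled across the training years so inter-annual
contrast survives. CPUE-based, unit-free suitability is the standard
fisheries HSI construction; catch- and effort-based targets are available
as configuration alternatives. A stratum with no CPUE contrast gets HSI
0.5 everywhere, with a warning. Min–max normalization is deliberately
sensitive to the stratum maximum; with multiplicative catch noise this
compresses the upper range, which is one reason predicted surfaces are
conservative near 1.

## The ensemble

Both model stages use a bagged regression-tree ensemble (random forest):
each tree grows on a bootstrap resample considering 4 candidate covariates
per split (`mtry = 4`), 1000 trees by default, minimum leaf size 5 (the
source setting is silent on leaf size; 5 is sklearn-conventional and
exposed). The implementation is scikit-learn's `RandomForestRegressor`
behind the package's own `ModelSpec`/`FittedSDM` surface; any conforming
bagged ensemble would do, and the contract — seeded determinism,
predictions bounded by the training response range, non-negative
importances — is what the tests pin down. `mtry` stays 4 in the coupled
stage even though the covariate count grows by one, matching the single
published setting.

The coupled model is fit one-pass, with no fixed-point iteration: species
A's coupled model consumes species B's *single-species* regional
prediction, never a coupled surface (the role tag on every surface enforces
this, so accidental ic→ic chaining is a hard error). The biotic covariate
is injected at fished cells by exact (cell, year, month) lookup — the
literal construction, with no spatial smoothing.

## Validation

Explanatory power is measured by repeated random 80/20 holdout: each
iteration refits the ensemble on the training split and scores
R² = 1 − SSE/SST on the test split. (The source description mixes the
"80/20" and "leave-one-out" vocabularies; repeated random holdout is the
only reading consistent with both the split ratio and the iteration count,
and is what is implemented.) R² is computed per month with per-month
refits — matching the per-month presentation of the comparison — with
pooled-month validation available via configuration. The iteration split is
a pure function of (seed, iteration, n), so the single-species and coupled
models are scored on identical splits and their per-iteration difference
isolates the biotic covariate. The paired Wilcoxon p-values on those
differences reproduce the usual star presentation (* p<0.05, ** p<0.01,
**** p<0.0001); because holdout replicates share training data they are
not independent, so the p-values are descriptive and labelled as such in
every report.

Field validation uses effort concentration: the fraction of total fishing
days in cells at or above HSI 0.6 ("optimal habitat"), and the fraction of
high-effort cells (≥ 40 days) lying in the top occupied habitat class.

## Habitat analysis

Suitability is classified into five fixed intervals with the last bin
closed ([0.8, 1] is class 5, so HSI = 1 does not spill into a sixth class);
classes 4–5 are optimal habitat. Cohabitation surfaces combine the two
coupled predictions cellwise; the combiner is genuinely underdetermined in
the source material, so the package defaults to the geometric mean
(symmetric, [0,1]-preserving, zero when either species finds a cell
unsuitable) with `min` and `product` as alternatives, and records the rule
in every output's metadata. Correlations are Pearson r over jointly
unmasked cells, pairwise-complete, never imputed.

## The synthetic study

Because the real logbooks are proprietary, the generator is a first-class
module whose defaults define the bundled study:

- **Environment**: surface temperature = 26 °C at 34° N minus 1 °C per
  degree of latitude, plus a seasonal cosine (peak August), a per-year
  offset, and a smooth Gaussian random field (σ = 0.8 °C, ~2-cell
  correlation length); deeper levels subtract a fixed mean lapse
  (2.5/5/7/8.5 °C at 50/100/150/200 m) plus smaller noise. SSH, SSS and
  log-Chl-a are gradient-plus-GRF fields; U and V are GRFs around a weak
  mean flow; EKE is computed, not drawn; ONI is an AR(1) month series and
  SSTA white monthly noise.
- **Species**: unimodal (Gaussian) response curves combined by weighted
  geometric mean. The sardine-like species occupies a productivity/front
  niche on the *small-scale* fields (Chl-a 0.8±0.22 mg m⁻³, EKE
  0.02±0.01, U 0.2±0.12, V 0.05±0.12 m s⁻¹), so its true field has fine
  spatial texture; the mackerel-like species tolerates a broad subsurface
  band (T₅₀ 13±9 °C, SSS 34±2) so its *own* environmental signal is weak.
- **Coupling**: truth_B = base_B · (1 + γ·base_A) / (1 + γ), clipped to
  [0, 1]. The renormalization by the largest attainable factor matters:
  without it the modifier saturates the unit interval over exactly the
  cells where fleets fish, and the between-species signal the workflow is
  supposed to recover is clipped away. Default γ_B = 0.8, γ_A = 0
  (asymmetric interaction); an additive form is available.
- **Observation**: each fleet spends a monthly effort budget in multi-day
  vessel-trips allocated by one multinomial draw with cell probabilities ∝
  truth^k (k = 3), restricted to cells above a detection floor; the budget
  is conserved exactly. Trips last 15 days (one truncated trip absorbs any
  remainder), which is what lets single good cells accumulate the ≥ 40
  fishing days the concentration analysis discusses; day-by-day allocation
  (`trip_days = 1`) is the degenerate special case. Catch per record is
  q·effort·truth·exp(σz − σ²/2) with q = 15 t/day and σ = 0.10. The
  sardine-like fleet surveys broadly (5000 days/month, floor 0.05); the
  mackerel-like fleet is smaller and concentrated (1300 days/month, floor
  0.2), mirroring the asymmetry in real per-species sample sizes. This
  yields ≈ 330 fished cells per month for the broadly surveyed species and
  ≈ 85 for the concentrated one — ≈ 2000–8000 training rows per species
  over four years, the scale of real logbook studies.

What the generator does *not* emulate: ocean dynamics (no advection or
coherent eddies), vessel economics or port behavior, species beyond two,
spatial autocorrelation of catch noise, and any latent driver of
distribution outside the 13 covariates. That last point is a real
limitation with a real consequence: in this generator each species' truth
is a deterministic function of the covariates, so a single-species model
could in principle learn everything, and the coupled model's gain is purely
a finite-sample efficiency gain (the competitor's model transfers
covariate-response structure learned from its own, larger sample). Passing
tests therefore demonstrate that the pipeline recovers an injected
interaction at realistic sample sizes — not that biotic covariates add
information no abiotic model could ever contain.

## Problem sizes and numerical choices

- Tests and the acceptance script run the study at a scaled setting chosen
  once — 100-tree ensembles and 10 holdout iterations instead of
  1000 × 100 — so the whole suite completes in minutes on one CPU; gains of
  the size the generator induces (≈ 0.06 R²) are insensitive to tree count
  beyond ~100, and 60 pooled split-matched differences give the Wilcoxon
  test ample resolution. The coupling power/null properties use 10
  independent root seeds.
- All randomness descends from one root seed through named, crc32-keyed
  substreams (generator / trees / splits), so stages re-run independently
  yet reproducibly, and derived seeds stay below 2³¹.
- Holdout iterations whose test stratum has zero response variance are
  recorded as missing, never silently dropped or imputed.
- An all-zero pairwise difference vector makes the Wilcoxon statistic
  undefined; the comparison reports p = 1 in that case.
- Tree-mean predictions of a [0, 1] response cannot leave [0, 1]; the clip
  in `predict` is a formal guard and a test asserts it is a no-op.
- NetCDF I/O uses xarray's scipy backend (netCDF3 classic); model binaries
  are pickles with JSON sidecars carrying full provenance.

## Known limitations

- Per-species CPUE is not vessel-standardized (no catchability GLM); the
  synthetic fleet is homogeneous, so this costs nothing here but would
  matter on real logbooks.
- Holdout splits are random, not spatially blocked; with spatially
  autocorrelated fields this overstates absolute R² (the ss/ic *difference*
  is less affected, being split-matched).
- The cohabitation combiner is a documented stand-in for an unspecified
  construction; conclusions that depend on the combiner's exact form
  should be checked under all three rules.
- The effort-concentration fractions of the predicted surfaces are
  conservative because min–max-normalized targets compress the upper range
  (see "Training target"); the concentration *logic* is validated against
  the generator's truth instead.
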