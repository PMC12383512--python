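# icsdm — interspecific-competition species distribution modelling

`icsdm` builds habitat-suitability models for two interacting pelagic fish
species — a sardine-like and a mackerel-like species on the Northwest
Pacific high-seas fishing grounds — from purse-seine logbook records and
monthly gridded ocean covariates, and quantifies how much of each species'
distribution is carried by the *other* species' distribution rather than by
the abiotic environment alone.

The workflow is the stacked ("biotic covariate") SDM construction used in
fisheries ecology:

1. **Gridding.** Logbook records (date, position, catch in tons, effort
   days, hauls, vessel) are binned to a 0.25° lattice; catch and effort are
   summed per (species, cell, month, year) and CPUE = Σcatch/Σeffort. The
   training target is the empirical habitat-suitability index
   HSI = (CPUE − min)/(max − min), min–max taken within each
   (species, month) stratum pooled over training years, so HSI ∈ [0, 1].
2. **Single-species models (ssSDM).** A bagged regression-tree ensemble
   (random forest; 1000 trees, 4 candidate covariates per split) maps the
   13 covariates — temperature at 0/50/100/150/200 m, SSH, SSS, Chl-a, U,
   V, EKE, SSTA, ONI — to the empirical HSI at fished cells.
3. **Regional prediction and coupling (icSDM).** Each species' fitted
   model is evaluated over the whole study window; the competitor's
   predicted regional HSI is then injected into the other species' model
   as one extra biotic covariate (`hsi_other`) and the model is refit.
4. **Validation.** 100 repeated random 80/20 holdouts per month, with the
   single-species and coupled models scored on *identical* splits, so the
   per-iteration R² difference isolates the biotic covariate (paired
   Wilcoxon for the significance stars). Effort concentration — the share
   of fishing days in predicted optimal habitat (HSI ≥ 0.6) — is the
   field-validation statistic.
5. **Habitat analysis.** Surfaces are cut into the five standard classes
   ([0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1]); cohabitation
   surfaces combine the two species cellwise (geometric mean by default);
   monthly Pearson correlations measure between- and within-species
   habitat co-variation.

Real purse-seine logbooks are proprietary, so the package ships a
first-class synthetic-data module: smooth monthly covariate fields, two
species with known unimodal response curves, a tunable interspecific
coupling γ (species B's true suitability is
`base_B · (1 + γ·base_A) / (1 + γ)`), and an effort-allocation observation
process (effort ∝ truth^k in multi-day vessel trips, catch =
q·effort·truth·lognormal noise). Every downstream claim is tested against
this known truth.

## Worked example

```python
from icsdm import StudyConfig, simulate_study, fit_stage
from icsdm.workflow import coupling_experiment

# the bundled study: 44x76-cell grid, 2017-2020 training, 2021 prediction,
# coupling gamma_B = 0.8 (scaled ensemble for a quick run)
res = coupling_experiment(seed=1, gamma_b=0.8, n_trees=100, iterations=10)
print(f"rows: {res['n_rows']}")
print(f"holdout R2  ss: {res['r2_ss_mean']:.3f}  ic: {res['r2_ic_mean']:.3f}")
print(f"mean gain dR2: {res['mean_delta']:+.3f}  (Wilcoxon p = {res['p']:.2e})")
```

prints

```
rows: 2049
holdout R2  ss: 0.594  ic: 0.658
mean gain dR2: +0.064  (Wilcoxon p = 1.80e-11)
```

i.e. on ~2000 coupled-species training cell-months, adding the competitor's
predicted suitability raises held-out explanatory power from 0.59 to 0.66 —
the coupled model recovers the interspecific signal the generator injected.
Re-running with `gamma_b=0.0` gives a mean gain of +0.000 (p = 0.99): with
no true interaction the biotic covariate is inert.

The same study is scriptable from the shell:

```bash
icsdm simulate --config run.yaml --seed 1
icsdm grid     --config run.yaml --seed 1
icsdm fit      --config run.yaml --seed 1
icsdm validate --config run.yaml --seed 1
icsdm analyze  --config run.yaml --seed 1 --plots
```

Each command records its outputs (logbook CSV, NetCDF covariate stacks and
suitability surfaces, model artifacts with JSON sidecars, validation and
correlation reports) in a manifest with sha256 hashes; the same config and
seed reproduce the manifest byte for byte.

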