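# Bundled study design at a quick-run scale: full 0.25-degree window,
# two training years, one prediction year, light ensemble.
grid:
  lat_min: 34.0
  lat_max: 45.0
  lon_min: 144.0
  lon_max: 163.0
  resolution: 0.25
study:
  train_years: [2017, 2018]
  predict_year: 2019
  months: [6, 7, 8, 9, 10, 11]
  gamma_b: 0.8
  n_trees: 100
  iterations: 10
  rule: geometric_mean
out_dir: runs/example
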