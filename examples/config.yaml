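# Example run configuration.
# Sections: scenario (generator), regimes, weights, estimation, cv.

scenario:
  n_patients: 2000
  seed: 12345
  horizon_days: 30

regimes:
  # omit `indices` to evaluate the full 81-regime grid
  indices: [1, 9, 27, 41, 81]

weights:
  # pooled logistic covariates (main effects); defaults shown
  daily_covariates:
    - potassium
    - ph
    - k_ge_60
    - ph_lt_720
    - uo_lt_05
    - uo_stage3
    - olig2_met
    - sofa
    - creat_ratio
  baseline_covariates: [age]
  time_effect: spline        # spline | linear | none
  truncation_percentile: 1.0 # 1.0 = no truncation

estimation:
  variance_method: infinitesimal-jackknife
  n_boot_rrt: 500
  n_boot_risk_difference: 500
  seed: 0

cv:
  k_folds: 5
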