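calibration_target_qaly: 4.95
cohort_moments:
  age:
    mean: 58.23
    sd: 15.43
  cholesterol_mg_dL:
    mean: 154.77
    sd: 52.71
  furosemide_equiv_mg_day:
    mean: 99.57
    sd: 123.93
  has_icd:
    proportion: 0.565
  hemoglobin_g_dL:
    mean: 13.33
    sd: 1.99
  ischemic_etiology:
    proportion: 0.285
  lvef_pct:
    mean: 32.07
    sd: 13.62
  lymphocytes_pct:
    mean: 22.18
    sd: 9.07
  nyha_latent:
    mean: 0.0
    sd: 1.0
  on_ace_inhibitor:
    proportion: 0.455
  on_aldosterone_blocker:
    proportion: 0.712
  on_allopurinol:
    proportion: 0.136
  on_arb:
    proportion: 0.272
  on_beta_blocker:
    proportion: 0.894
  sbp_mmHg:
    mean: 110.36
    sd: 17.91
  sex_female:
    proportion: 0.22
  sodium_mEq_L:
    mean: 137.73
    sd: 3.06
  urate_mg_dL:
    mean: 7.97
    sd: 2.7
  weight_kg:
    mean: 83.39
    sd: 20.04
cohort_size: 1000
correlation_matrix:
- - 1.0
  - 0.0
  - 0.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.2
  - 0.0
  - 0.0
  - -0.1
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - -0.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.2
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.3
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - -0.3
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - -0.2
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - -0.3
  - 1.0
  - -0.15
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.2
  - 0.0
- - 0.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - -0.15
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - -0.15
  - 0.0
- - -0.1
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - -0.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.3
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.25
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.15
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.2
  - 0.0
  - 0.0
  - -0.15
  - 0.0
  - 0.0
  - 0.25
  - 0.15
  - 1.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - -0.2
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
deployment_ratio:
- 2
- 1
- 2
dirichlet_concentration: 500.0
discount_rate_annual: 0.015
drug_age_threshold: 65.0
horizon_months: 300
hosp_cost_mean: 8908.0
hosp_cost_sd: 16867.0
hosp_disutility: 0.059
hosp_disutility_ci:
- 0.0
- 0.11
hosp_prob_monthly:
- 0.0152
- 0.024
- 0.024
- 0.154
hosp_prob_ranges:
- - 0.008
  - 0.023
- - 0.012
  - 0.036
- - 0.012
  - 0.036
- - 0.077
  - 0.231
inhospital_mortality_monthly: 0.02
kit_monthly_cost:
  BYOE: 3.8
  BYOP: 18.87
  FK: 67.56
los_mean_days: 5.9
los_sd_days: 11.2
medly_fixed_site_cost: 102500.0
medly_operational_monthly: 44.67
medly_site_capacity: 1000
nyha_cutpoints:
- -1.0592769170824314
- 0.49808936995031894
- 2.7174380324971823
nyha_transition_matrix:
- - 0.977
  - 0.019
  - 0.004
  - 0.0
- - 0.008
  - 0.981
  - 0.01
  - 0.001
- - 0.0
  - 0.034
  - 0.96
  - 0.006
- - 0.0
  - 0.0
  - 0.055
  - 0.945
psa_iterations: 1000
readmission_scope: persistent
readmit_prob_30d: 0.159
readmit_prob_ci:
- 0.089
- 0.159
rr_applies_to_readmission: false
rr_hospitalization: 0.753
rr_hospitalization_ci:
- 0.634
- 0.879
rr_mortality: 0.81
rr_mortality_ci:
- 0.7
- 0.94
shfm:
  baseline_annual_hazard: 0.105
  centers:
    age: 58.23
    cholesterol_mg_dL: 154.77
    furosemide_equiv_mg_day: 99.57
    has_icd: 0.565
    hemoglobin_g_dL: 13.33
    ischemic_etiology: 0.285
    lvef_pct: 32.07
    lymphocytes_pct: 22.18
    nyha_class: 2.36
    on_ace_inhibitor: 0.455
    on_aldosterone_blocker: 0.712
    on_allopurinol: 0.136
    on_arb: 0.272
    on_beta_blocker: 0.894
    sbp_mmHg: 110.36
    sex_female: 0.22
    sodium_mEq_L: 137.73
    urate_mg_dL: 7.97
    weight_kg: 83.39
  coefficients:
    age: 0.0086
    cholesterol_mg_dL: -0.003
    furosemide_equiv_mg_day: 0.002
    has_icd: -0.27
    hemoglobin_g_dL: -0.034
    ischemic_etiology: 0.3
    lvef_pct: -0.03
    lymphocytes_pct: -0.022
    nyha_class: 0.47
    on_ace_inhibitor: -0.26
    on_aldosterone_blocker: -0.3
    on_allopurinol: 0.45
    on_arb: -0.16
    on_beta_blocker: -0.42
    sbp_mmHg: -0.008
    sex_female: -0.1
    sodium_mEq_L: -0.0163
    urate_mg_dL: 0.077
    weight_kg: -0.002
state_cost_components:
  drug:
  - 52.0
  - 52.0
  - 79.43
  - 208.16
  ed:
  - 0.0
  - 0.0
  - 62.83
  - 62.83
  gp:
  - 0.0
  - 0.0
  - 12.87
  - 12.87
  outpatient:
  - 97.0
  - 97.0
  - 97.0
  - 97.0
truncation_bounds:
  age:
  - 18.0
  - 100.0
  cholesterol_mg_dL:
  - 50.0
  - 500.0
  furosemide_equiv_mg_day:
  - 0.0
  - 2000.0
  hemoglobin_g_dL:
  - 4.0
  - 22.0
  lvef_pct:
  - 1.0
  - 100.0
  lymphocytes_pct:
  - 1.0
  - 60.0
  sbp_mmHg:
  - 60.0
  - 250.0
  sodium_mEq_L:
  - 110.0
  - 160.0
  urate_mg_dL:
  - 1.0
  - 20.0
  weight_kg:
  - 30.0
  - 250.0
unit_costs:
  drug_6mo:
    mean: 1248.96
    sd: 2233.52
  ed:
    mean: 377.0
    sd: 374.0
  gp:
    mean: 77.2
    sd: 0.0
  outpatient:
    mean: 291.33
    sd: 161.11
utilities_by_class:
- 0.81
- 0.72
- 0.59
- 0.508
utility_ranges:
- - 0.81
  - 0.9
- - 0.72
  - 0.83
- - 0.59
  - 0.74
- - 0.508
  - 0.59
utilization_median_6mo:
  ed:
  - 0
  - 0
  - 1
  - 1
  gp:
  - 0
  - 1
  - 2
  - 2
  outpatient:
  - 2
  - 1
  - 2
  - 2
wtp_grid:
- 0.0
- 1000.0
- 2000.0
- 3000.0
- 4000.0
- 5000.0
- 6000.0
- 7000.0
- 8000.0
- 9000.0
- 10000.0
- 11000.0
- 12000.0
- 13000.0
- 14000.0
- 15000.0
- 16000.0
- 17000.0
- 18000.0
- 19000.0
- 20000.0
- 21000.0
- 22000.0
- 23000.0
- 24000.0
- 25000.0
- 26000.0
- 27000.0
- 28000.0
- 29000.0
- 30000.0
- 31000.0
- 32000.0
- 33000.0
- 34000.0
- 35000.0
- 36000.0
- 37000.0
- 38000.0
- 39000.0
- 40000.0
- 41000.0
- 42000.0
- 43000.0
- 44000.0
- 45000.0
- 46000.0
- 47000.0
- 48000.0
- 49000.0
- 50000.0
- 51000.0
- 52000.0
- 53000.0
- 54000.0
- 55000.0
- 56000.0
- 57000.0
- 58000.0
- 59000.0
- 60000.0
- 61000.0
- 62000.0
- 63000.0
- 64000.0
- 65000.0
- 66000.0
- 67000.0
- 68000.0
- 69000.0
- 70000.0
- 71000.0
- 72000.0
- 73000.0
- 74000.0
- 75000.0
- 76000.0
- 77000.0
- 78000.0
- 79000.0
- 80000.0
- 81000.0
- 82000.0
- 83000.0
- 84000.0
- 85000.0
- 86000.0
- 87000.0
- 88000.0
- 89000.0
- 90000.0
- 91000.0
- 92000.0
- 93000.0
- 94000.0
- 95000.0
- 96000.0
- 97000.0
- 98000.0
- 99000.0
- 100000.0
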