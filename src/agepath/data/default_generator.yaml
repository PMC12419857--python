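# Default synthetic-cohort calibration, version 1.0.
# Biomarker models are linear in age with a shared latent frailty factor;
# values are in the same training units the packaged scoring coefficients
# expect. Transition intensities are calibrated so that after ~31 years of
# pre-baseline disease history (process_start_age -> mean baseline age) the
# baseline state mix is roughly 18% no condition / 55% single / 23% dual /
# 3% triple.
n_participants: 10000
seed: 0
age_range: [45.0, 70.0]
sex_ratio: 0.54           # proportion female
process_start_age: 25.0   # disorder process starts here; no deaths before baseline
followup_years: 14.0
frailty_sd: 1.0

# intercept is the value at age 0; mean at age a = intercept + age_slope * a
# (+ sex_offset if female). log_scale biomarkers are modelled on the natural
# log scale and exponentiated.
biomarker_models:
  sbp:                  {intercept: 114.8, age_slope: 0.45,   sex_offset: -4.0,  residual_sd: 15.0, frailty_loading: 0.30, unit: mmHg}
  fev1:                 {intercept: 4.74,  age_slope: -0.028, sex_offset: -0.70, residual_sd: 0.50, frailty_loading: -0.30, unit: L}
  total_cholesterol:    {intercept: 5.14,  age_slope: 0.010,  sex_offset: 0.20,  residual_sd: 1.00, frailty_loading: 0.15, unit: mmol/L}
  hba1c:                {intercept: 29.3,  age_slope: 0.12,   sex_offset: -0.50, residual_sd: 5.00, frailty_loading: 0.30, unit: mmol/mol}
  urea:                 {intercept: 3.72,  age_slope: 0.030,  sex_offset: -0.40, residual_sd: 1.30, frailty_loading: 0.20, unit: mmol/L}
  crp:                  {intercept: -2.57, age_slope: 0.012,  sex_offset: 0.10,  residual_sd: 1.00, frailty_loading: 0.35, unit: mg/dL, log_scale: true}
  alkaline_phosphatase: {intercept: 71.8,  age_slope: 0.20,   sex_offset: -2.0,  residual_sd: 25.0, frailty_loading: 0.25, unit: U/L}
  albumin:              {intercept: 48.4,  age_slope: -0.060, sex_offset: -0.50, residual_sd: 2.60, frailty_loading: -0.25, unit: g/L}
  creatinine:           {intercept: 66.6,  age_slope: 0.15,   sex_offset: -12.0, residual_sd: 13.0, frailty_loading: 0.20, unit: umol/L}
  glucose:              {intercept: 4.08,  age_slope: 0.020,  sex_offset: -0.10, residual_sd: 1.00, frailty_loading: 0.30, unit: mmol/L}
  lymphocyte_pct:       {intercept: 33.5,  age_slope: -0.080, sex_offset: 0.50,  residual_sd: 7.00, frailty_loading: -0.20, unit: '%'}
  mcv:                  {intercept: 80.6,  age_slope: 0.040,  sex_offset: 0.30,  residual_sd: 5.00, frailty_loading: 0.15, unit: fL}
  rdw:                  {intercept: 12.8,  age_slope: 0.012,  sex_offset: 0.0,   residual_sd: 0.95, frailty_loading: 0.30, unit: '%'}
  wbc:                  {intercept: 6.62,  age_slope: 0.005,  sex_offset: 0.10,  residual_sd: 1.90, frailty_loading: 0.25, unit: 1e9 cells/L}

# Baseline log intensity (per year) for each allowed transition.
# Death edges are relative log offsets added to the Gompertz age term.
transition_log_intensities:
  none->single: -2.85
  single->dual: -3.90
  dual->triple: -4.60
  single->death: 0.00
  dual->death: 0.45
  triple->death: 0.80

# log hazard ratio per SD of the latent frailty, per transition
transition_frailty_loghr:
  none->single: 0.25
  single->dual: 0.25
  dual->triple: 0.25
  single->death: 0.35
  dual->death: 0.35
  triple->death: 0.35

# death intensity at age a (before edge offsets / frailty):
# exp(rate_intercept + age_slope * a)
gompertz_mortality:
  rate_intercept: -11.1
  age_slope: 0.085

# MCAR missingness per covariate column (echoes typical cohort missingness)
missingness_rates:
  education: 0.011
  income: 0.143
  townsend: 0.012
  alcohol: 0.002
  smoking: 0.005
  bmi_category: 0.002
  physical_activity: 0.223
  diet_score: 0.083
  no2: 0.013
  nox: 0.013
  pm25: 0.049
  pm10: 0.049
missingness_mechanism: mcar   # or mar_age
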