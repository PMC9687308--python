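# Base-case inputs, Portuguese payer perspective, 2020 euros.
# Proportions are fractions; SBP mm Hg; TC/HDL mg/dL; hsCRP mg/L;
# eGFR mL/min/1.73m^2. Epidemiology defaults beyond the published table
# are documented in polypillce.synthetic_data.EPI_DEFAULTS.
population:
  starting_age: 69.37
  male_frac: 0.618
  smoker_frac: 0.174
  diabetes_frac: 0.278
  afib_frac: 0.132
  lvh_frac: 0.062
  sbp: 145.1
  tc: 190.8
  hdl: 45.2
  hscrp: 2.2
  egfr: 74.3
  aaa_history_frac: 0.021
  pad_history_frac: 0.032
  years_since_first_event: 1.0
  post_chd_weight: 0.579
  post_stroke_weight: 0.421
  cohort_size: 1000
arms:
  intervention:
    arm_name: polypill
    sbp_delta: 1.80
    tc_delta: 5.28
    hdl_delta: 4.01
    annual_drug_cost: 84.62
  comparator:
    arm_name: monocomponents
    sbp_delta: 0.0
    tc_delta: 0.0
    hdl_delta: 0.0
    annual_drug_cost: 63.44
costs:
  acute_chd_nonfatal: 4560.1
  acute_chd_fatal: 3153.5
  acute_stroke_nonfatal: 8653.3
  acute_stroke_fatal: 6381.2
  annual_post_chd: 643.3
  annual_post_stroke: 534.8
utilities:
  chronic_chd: 0.84
  chronic_stroke: 0.69
  acute_chd: 0.76
  acute_stroke: 0.63
  death: 0.0
epidemiology:
  chd_share_of_events: 0.579
  case_fatality_chd: 0.16
  case_fatality_stroke: 0.18
  rr_recurrent_stroke: 2.3
  life_table: synthetic
settings:
  horizon_years: 32
  discount_rate: 0.04
  wtp_threshold: 30000.0
  risk_model_name: smart
  first_year_cycle_len: 0.25
  later_cycle_len: 1.0
  half_cycle_correction: true
risk_models:
  smart:
    file: smart_coefficients.csv
    baseline_survival: 0.8107
    horizon_years: 10.0
  framingham_chd:
    file: framingham_chd_synthetic.csv
    baseline_survival: 0.88936
    horizon_years: 10.0
  framingham_stroke:
    file: framingham_stroke_synthetic.csv
    baseline_survival: 0.90
    horizon_years: 10.0
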