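# Base-case inputs of the T-DXd vs physician's-choice chemotherapy
# cost-effectiveness model for HER2-low advanced breast cancer (US payer
# perspective, 2022 USD).
#
# Scalars carry {base, low, high, family}: the deterministic value, the
# one-way sensitivity range and the probabilistic-sensitivity distribution
# family (moment-matched to base and sd = (high - low)/3.92).
#
# Weibull survival parameters are on the hazard scale, S(t) = exp(-scale*t^shape),
# with one fitted time unit = one 6-week model cycle (fitted_unit_weeks).
#
# treatment_duration_factor values are calibrated so each arm's discounted
# total cost reproduces the published model's totals; see docs/methods.md.
name: destiny_b04
shared:
  admin_cost_per_cycle: {base: 352, low: 282, high: 422, family: gamma}
  followup_cost_per_cycle: {base: 1980, low: 1584, high: 2376, family: gamma}
  bsc_cost_per_cycle: {base: 3358, low: 2686, high: 4029, family: gamma}
  ihc_cost: {base: 123, low: 98, high: 148, family: gamma}
  terminal_cost: {base: 2844, low: 2275, high: 3413, family: gamma}
  utility_pfs: {base: 0.700, low: 0.560, high: 0.840, family: beta}
  utility_pd: {base: 0.500, low: 0.400, high: 0.600, family: beta}
  disutilities:
    neutropenia: {base: 0.090, low: 0.072, high: 0.108, family: beta}
    leukopenia: {base: 0.090, low: 0.072, high: 0.108, family: beta}
    anemia: {base: 0.120, low: 0.096, high: 0.144, family: beta}
    thrombocytopenia: {base: 0.122, low: 0.098, high: 0.146, family: beta}
    fatigue: {base: 0.290, low: 0.232, high: 0.348, family: beta}
    aminotransferase_increase: {base: 0.308, low: 0.246, high: 0.370, family: beta}
  weight_kg: {base: 74, low: 59, high: 89, family: normal}
  bsa_m2: {base: 1.82, low: 1.46, high: 2.18, family: normal}
  annual_discount: {base: 0.03, low: 0, high: 0.05, family: uniform}
  cycle_length_weeks: 6
  fitted_unit_weeks: 6
  horizon_years: 15
  wtp: 150000
  discount_lys: false
  half_cycle: false
  followup_in_pfs_only: false
arms:
  chemo:
    drug_cost_per_cycle: {base: 7607, low: 6086, high: 9128, family: gamma}
    ae_cost_total: {base: 7870, low: 6296, high: 9444, family: gamma}
    ae_risks:
      neutropenia: {base: 0.407, low: 0.326, high: 0.488, family: beta}
      leukopenia: {base: 0.192, low: 0.154, high: 0.230, family: beta}
      aminotransferase_increase: {base: 0.081, low: 0.065, high: 0.097, family: beta}
    bsc_rate: {base: 0.081, low: 0.065, high: 0.097, family: beta}
    weight_scaled: false
  tdxd:
    drug_cost_per_cycle: {base: 20114, low: 16091, high: 24137, family: gamma}
    ae_cost_total: {base: 2585, low: 2068, high: 3102, family: gamma}
    ae_risks:
      neutropenia: {base: 0.137, low: 0.110, high: 0.164, family: beta}
      anemia: {base: 0.081, low: 0.065, high: 0.097, family: beta}
      fatigue: {base: 0.075, low: 0.060, high: 0.090, family: beta}
      leukopenia: {base: 0.065, low: 0.052, high: 0.078, family: beta}
      thrombocytopenia: {base: 0.051, low: 0.041, high: 0.061, family: beta}
    bsc_rate: {base: 0.162, low: 0.130, high: 0.194, family: beta}
    weight_scaled: true
cohorts:
  overall:
    chemo:
      os: {scale: 0.011708, shape: 1.432984}
      pfs: {scale: 0.164483, shape: 0.903477}
      treatment_duration_factor: 1.0
    tdxd:
      os: {scale: 0.007249, shape: 1.431054}
      pfs: {scale: 0.057066, shape: 1.074695}
      treatment_duration_factor: 0.759
  hr_pos:
    chemo:
      os: {scale: 0.011763, shape: 1.393105}
      pfs: {scale: 0.141586, shape: 0.945576}
      treatment_duration_factor: 1.0
    tdxd:
      os: {scale: 0.004488, shape: 1.577038}
      pfs: {scale: 0.049346, shape: 1.116918}
      treatment_duration_factor: 0.834
  hr_neg:
    chemo:
      os: {scale: 0.050763, shape: 1.129492}
      pfs: {scale: 0.25686, shape: 0.8906}
      treatment_duration_factor: 0.881
    tdxd:
      os: {scale: 0.026802, shape: 1.097747}
      pfs: {scale: 0.11992, shape: 0.84977}
      treatment_duration_factor: 0.6448
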