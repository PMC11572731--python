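# Study-calibrated defaults: 117 BA / 123 WA patients, covariate
# distributions matched to the published group summaries, structural
# coefficients alpha = 4.65, beta = 0.021, gamma = 0.60, and a count-mode
# rim-probability model calibrated to mean PRL percentages 8.01 / 3.40 and
# prevalences 0.55 / 0.39.
seed: 1
generator:
  n_ba: 117
  n_wa: 123
  mode: linear
  seed: 1
  age_mean: {BA: 44.55, WA: 43.00}
  age_sd: {BA: 12.09, WA: 10.58}
  male_frac: {BA: 0.23931623931623933, WA: 0.3089430894308943}
  duration_mean: {BA: 11.00, WA: 10.60}
  duration_sd: {BA: 7.52, WA: 8.30}
  dmt_probs:
    BA: {higher: 0.5042735042735043, lower: 0.32478632478632485, untreated: 0.17094017094017092}
    WA: {higher: 0.5203252032520326, lower: 0.3333333333333333, untreated: 0.14634146341463414}
  income_mean: {BA: 66085.81, WA: 120000.00}
  income_sd: {BA: 29486.83, WA: 40388.69}
  non_prl_volume_mean: {BA: 8029.30, WA: 3600.00}
  non_prl_volume_sd: {BA: 9336.09, WA: 5778.24}
  flair_mean: {BA: 23.83, WA: 22.00}
  flair_sd: {BA: 20.77, WA: 20.31}
  med_intercept: 5.3102
  alpha: 4.65
  med_age: -0.05
  med_dmt_lower: 0.5
  med_dmt_untreated: 0.5
  med_resid_sd: {BA: 15.25, WA: 7.50}
  out_intercept: -0.8627
  gamma: 0.60
  beta: 0.021
  out_age: 0.05
  out_dmt_lower: -0.58
  out_dmt_untreated: -0.31
  out_non_prl_volume: 5.0e-5
  out_resid_sd: {BA: 1.9, WA: 1.5}
  count_logit_intercept: -3.683908
  count_race_effect: 0.646573
  count_overdisp_sd: {BA: 1.261789, WA: 0.862427}
  confounder_strength: 0.0
  round_edss: false
mediation:
  n_boot: 25000
  ci_level: 0.95
  stratified: false
sensitivity:
  rho_min: -0.9
  rho_max: 0.9
  step: 0.01
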