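# First-line sugemalimab + chemotherapy vs chemotherapy for metastatic
# nonsquamous NSCLC (Chinese healthcare-system perspective).
# Single source of the published model inputs used throughout the package:
# Weibull survival parameters per arm/endpoint (time in 21-day cycles),
# 2022 unit drug prices (USD), grade>=3 adverse-event costs/incidences,
# health-state utilities and AE disutilities, per-cycle follow-up /
# subsequent-therapy / best-supportive-care costs, dosing covariates,
# 5% annual discounting and a WTP of 3x 2021 per-capita GDP.

grid:
  horizon_years: 10.0
  cycle_length_days: 21.0
discount_rate: 0.05
wtp: 37663.26
time_unit: cycle
intervention: sugemalimab
comparator: chemotherapy

dosing:
  weight_kg: 65.0
  bsa_m2: 1.72
  crcl_ml_min: 70.0
  pemetrexed_mg_per_m2: 500.0
  carboplatin_auc: 5.0
  sugemalimab_flat_mg: 1200.0

prices:
  sugemalimab_per_mg: 3.08
  pemetrexed_per_mg: 1.672
  carboplatin_per_mg: 0.041

utilities:
  pfd: 0.71
  pd: 0.67
  dead: 0.0

ae_events:
  anemia:
    cost_per_episode: 531.7
    disutility: 0.073
  wbc_decreased:
    cost_per_episode: 461.5
    disutility: 0.2
  platelet_decreased:
    cost_per_episode: 3551.7
    disutility: 0.108

costs:
  followup_per_cycle: 55.60
  subsequent_per_cycle: 854.05
  bsc_per_cycle: 337.50

toggles:
  eval_point: cycle-end
  half_cycle_correction: false
  ae_cost_mode: per-treatment-cycle
  ae_disutility_mode: once
  followup_state: pfd
  treatment_duration_rule: until-progression
  curve_fit_loss: squared-survival

strategies:
  sugemalimab:
    os: {family: weibull, params: {shape: 1.15, rate: 0.017}}
    pfs: {family: weibull, params: {shape: 1.16, rate: 0.047}}
    combo_cycles: 4
    combo_drugs: [sugemalimab, pemetrexed, carboplatin]
    maintenance_drugs: [sugemalimab, pemetrexed]
    ae_incidence: {anemia: 0.13, wbc_decreased: 0.14, platelet_decreased: 0.11}
    subsequent_therapy_share: 0.44
    treatment_cap_cycles: 10.5   # median 7.2 months of study treatment
  chemotherapy:
    os: {family: weibull, params: {shape: 1.36, rate: 0.015}}
    pfs: {family: weibull, params: {shape: 1.29, rate: 0.059}}
    combo_cycles: 4
    combo_drugs: [pemetrexed, carboplatin]
    maintenance_drugs: [pemetrexed]
    ae_incidence: {anemia: 0.69, wbc_decreased: 0.17, platelet_decreased: 0.10}
    subsequent_therapy_share: 0.62
    treatment_cap_cycles: 6.7    # median 4.6 months of study treatment

# One-way ranges: +/-25% where printed, except the sugemalimab price
# (-50% only) and the trial-reported dosing-covariate and discount ranges.
dsa_ranges:
  - {path: prices.sugemalimab_per_mg, low: 1.54, high: 3.08, distribution: gamma}
  - {path: prices.pemetrexed_per_mg, low: 1.337, high: 2.006, distribution: gamma}
  - {path: prices.carboplatin_per_mg, low: 0.032, high: 0.049, distribution: gamma}
  - {path: ae_events.anemia.cost_per_episode, low: 425.36, high: 638.04, distribution: gamma}
  - {path: ae_events.wbc_decreased.cost_per_episode, low: 369.2, high: 553.08, distribution: gamma}
  - {path: ae_events.platelet_decreased.cost_per_episode, low: 2841.36, high: 4246.04, distribution: gamma}
  - {path: utilities.pfd, low: 0.53, high: 0.89, distribution: beta}
  - {path: utilities.pd, low: 0.50, high: 0.84, distribution: beta}
  - {path: ae_events.anemia.disutility, low: 0.058, high: 0.088, distribution: beta}
  - {path: ae_events.wbc_decreased.disutility, low: 0.16, high: 0.24, distribution: beta}
  - {path: ae_events.platelet_decreased.disutility, low: 0.086, high: 0.13, distribution: beta}
  - {path: costs.followup_per_cycle, low: 27.8, high: 83.4, distribution: gamma}
  - {path: costs.subsequent_per_cycle, low: 427.02, high: 1281.08, distribution: gamma}
  - {path: costs.bsc_per_cycle, low: 168.75, high: 506.25, distribution: gamma}
  - {path: dosing.weight_kg, low: 32.5, high: 97.5, distribution: normal}
  - {path: dosing.bsa_m2, low: 0.86, high: 2.58, distribution: normal}
  - {path: dosing.crcl_ml_min, low: 35.0, high: 105.0, distribution: normal}
  - {path: discount_rate, low: 0.0, high: 0.08, distribution: beta, support: [0.0, 0.08]}

psa:
  n_draws: 10000
  seed: 20181213
  incidence_sd_fraction: 0.2
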