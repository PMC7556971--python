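# Default model inputs: one block per parameter-table row, plus structural
# constants, accrual settings, published reference outputs, and the frozen
# Weibull calibration (regenerate with `fruqcea calibrate`).
#
# Ranges are deterministic one-way SA bounds (+/-20% of base unless the source
# table printed its own range); Beta/Gamma PSA distributions are built from
# (base, range) by the method of moments with SD = range/3.92.
# The diarrhea management-cost range is reconstructed as +/-20% of base (the
# printed range is not legible in the source table).
parameters:
  - {name: prob_hypertension_fruq, base: 0.212, low: 0.170, high: 0.254, distribution: beta, units: probability}
  - {name: prob_hand_foot_syndrome_fruq, base: 0.108, low: 0.086, high: 0.130, distribution: beta, units: probability}
  - {name: prob_diarrhea_fruq, base: 0.029, low: 0.0232, high: 0.0348, distribution: beta, units: probability}
  - {name: prob_platelet_count_decreased_fruq, base: 0.025, low: 0.02, high: 0.03, distribution: beta, units: probability}
  - {name: prob_hypertension_bsc, base: 0.022, low: 0.0176, high: 0.0264, distribution: beta, units: probability}
  - {name: cost_bsc_per_cycle, base: 1415.4, low: 1022.8, high: 2021.5, distribution: gamma, units: USD per cycle}
  - {name: cost_fruquintinib_post, base: 1128.8, low: 903.0, high: 1354.5, distribution: gamma, units: USD per cycle}
  - {name: cost_fruquintinib_pre, base: 3408.5, low: 2726.8, high: 4090.2, distribution: gamma, units: USD per cycle}
  - {name: cost_hypertension, base: 59.1, low: 47.28, high: 70.92, distribution: gamma, units: USD one-off}
  - {name: cost_hand_foot_syndrome, base: 134.4, low: 107.58, high: 161.38, distribution: gamma, units: USD one-off}
  - {name: cost_diarrhea, base: 844.3, low: 675.44, high: 1013.16, distribution: gamma, units: USD one-off}
  - {name: cost_platelet_count_decreased, base: 3551.7, low: 3156.8, high: 3980.2, distribution: gamma, units: USD one-off}
  - {name: utility_baseline, base: 0.66, low: 0.59, high: 0.735, distribution: beta, units: utility}
  - {name: duration_hand_foot_syndrome, base: 14.0, low: 11.2, high: 16.8, distribution: gamma, units: days}
  - {name: duration_diarrhea, base: 5.0, low: 4.0, high: 6.0, distribution: gamma, units: days}
  - {name: duration_hypertension, base: 0.0, low: 0.0, high: 0.0, distribution: fixed, units: days}
  - {name: duration_platelet_count_decreased, base: 0.0, low: 0.0, high: 0.0, distribution: fixed, units: days}
  - {name: disutility_hand_foot_syndrome, base: 0.116, low: 0.093, high: 0.139, distribution: beta, units: utility magnitude}
  - {name: disutility_diarrhea, base: 0.103, low: 0.082, high: 0.123, distribution: beta, units: utility magnitude}
  - {name: disutility_hypertension, base: 0.0, low: 0.0, high: 0.0, distribution: fixed, units: utility magnitude}
  - {name: disutility_platelet_count_decreased, base: 0.0, low: 0.0, high: 0.0, distribution: fixed, units: utility magnitude}
  # no PSA distribution for the discount rate; varied only in one-way SA
  - {name: discount_rate_annual, base: 0.03, low: 0.00, high: 0.05, distribution: fixed, units: rate}

constants:
  cycle_length_days: 28.0
  dosing_days_per_cycle: 21.0
  wtp_threshold: 27130.0
  unit_drug_cost_post: 53.8
  unit_drug_cost_pre: 162.3
  median_os_fruq: 9.3
  median_os_placebo: 6.6
  os_hazard_ratio: 0.65
  median_treatment_duration: 3.7

settings:
  max_cycles: 260
  stop_threshold: 1.0e-3
  cost_timing: end
  utility_timing: start
  concurrent_bsc_while_on_treatment: true
  pre_negotiation_paid_cycles: [1, 2, 5]
  half_cycle_correction: false

reference:
  cost_fruq_post: 20750.9
  cost_placebo: 12042.2
  qaly_fruq: 0.6404
  qaly_placebo: 0.4776
  incremental_cost_post: 8708.7
  incremental_effect: 0.16275
  icer_post: 53508.7
  cost_fruq_pre: 23590.0
  incremental_cost_pre: 11547.8
  icer_pre: 70952.6

# Frozen Weibull OS shapes per arm (scale tied to the arm's median OS above);
# produced by fruqcea.calibration.calibrate against the reference arm totals.
calibration:
  fruquintinib: 1.2949148591749053
  placebo: 1.2056940121382762
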