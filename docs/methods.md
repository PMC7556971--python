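# Methods

This document records the modelling choices behind `fruqcea`, in particular
the ones the source publication leaves unstated and that this implementation
had to pin down by calibration.

## 1. Model structure

A cohort Markov model compares fruquintinib + best supportive care (BSC)
against BSC alone for third-line metastatic colorectal cancer.

- **States.** Fruquintinib arm: `on_treatment` → `bsc` → `dead` (death is
  reachable from both alive states; `bsc` is not left except by death).
  BSC arm: `bsc` → `dead`. The full cohort starts in the arm's initial alive
  state.
- **Cycle.** 28 days (one 21-days-on / 7-days-off fruquintinib course).
  One cycle = 28/30.4375 ≈ 0.9199 months = 28/365.25 years.
- **Horizon.** Lifetime: the simulation stops when the alive fraction falls
  below 10⁻³ or after 260 cycles (~20 years), whichever comes first.

## 2. Survival and transitions

Overall survival (OS) in each arm follows a Weibull curve
S(t) = exp(−(t/λ)^k) with t in months. The scale λ is pinned to the trial
median OS (9.3 months fruquintinib, 6.6 months BSC) via
λ = median / (ln 2)^(1/k); the shape k is a free parameter set by
calibration (§4). The per-cycle death probability between cycles t and t+1 is
P(t) = 1 − S((t+1)Δ)/S(tΔ), identical in both alive states, so the alive
fraction of the cohort telescopes exactly to S(tΔ) (a tested invariant).

Treatment discontinuation is exponential with median 3.7 months
(per-cycle probability ≈ 0.158). Within a transition, death is applied first
and discontinuation to the survivors; because death is state-independent the
two mechanisms commute and the ordering does not affect the trace.

## 3. Economics

- **Costs per cycle.** Fruquintinib 3,408.5 USD (pre-negotiation list price)
  or 1,128.8 USD (post-negotiation) while on treatment; BSC 1,415.4 USD per
  alive cycle. While on treatment the BSC cost is charged concurrently with
  the drug (§4 explains why). Under the pre-negotiation patient-assistance
  scheme the drug is charged only in treated cycles 1, 2 and 5 (buy 3 + 2,
  get the rest free).
- **Adverse events.** Grade ≥3 events (hypertension, hand-foot syndrome,
  diarrhoea, decreased platelet count in the treated arm; hypertension only
  in the BSC arm) are applied as a one-off expected burden at model entry:
  cost = Σ pᵢ·cᵢ and QALY loss = Σ pᵢ·dᵢ·durationᵢ/365.25. Hypertension and
  platelet decrease carry zero disutility.
- **Utility.** 0.66 while alive, in either alive state.
- **Discounting.** 3% per annum, factor (1.03)^(−t·28/365.25); cycle 0 is
  undiscounted.
- **Decision metrics.** ICER = ΔCost/ΔQALY, net monetary benefit
  NMB(w) = w·ΔQALY − ΔCost, willingness-to-pay threshold 27,130 USD/QALY
  (3× Chinese per-capita GDP at the time of the analysis).

## 4. Calibration and accrual conventions

The source publication reports arm-level totals (costs 20,750.9 / 12,042.2
USD and QALYs 0.6404 / 0.4776) but not the fitted Weibull parameters or the
accrual conventions of its modelling software. Two things are therefore
derived rather than copied:

1. **Accrual conventions.** A systematic scan over timing conventions showed
   that the published arm totals are jointly reproducible only when costs
   accrue on **end-of-cycle** occupancy (rows 1..T of the trace), utilities
   on **start-of-cycle** occupancy (rows 0..T−1), and BSC cost is charged
   **concurrently** with the drug while on treatment. Other combinations
   leave the BSC arm's cost/QALY ratio ~11% off no matter the survival
   shape. These conventions are exposed as settings
   (`cost_timing`, `utility_timing`, `concurrent_bsc_while_on_treatment`,
   `half_cycle_correction`) so alternatives remain one config edit away.
2. **Weibull shapes.** With conventions fixed, each arm's shape k is found by
   bounded scalar minimisation (k ∈ [0.8, 2.5]) of the summed squared
   relative error of that arm's (cost, QALY) pair against the published
   totals. The search is deterministic; the frozen result
   (k ≈ 1.295 fruquintinib, k ≈ 1.206 BSC) ships in the default config and
   re-running `fruqcea calibrate` reproduces it (a tested fixed point).

**Residual disagreement.** The calibrated model matches each arm to within
0.5% and both simulated median OS values to within 0.01 months, and its
cumulative-hazard ratio at 12 months (~0.68) is consistent with the trial
hazard ratio 0.65. But the per-arm errors anti-correlate, so the
*incremental* quantities are less exact: incremental cost +1.5%, incremental
QALY −2.5%, post-negotiation ICER ≈ 55,715 vs published 53,508.7 (+4.1%).
The pre-negotiation arm cost (23,590 published) is unreachable by ~4% under
any exponential discontinuation consistent with the 3.7-month median — the
donation schedule caps how far pre- and post-negotiation costs can diverge.
`fruqcea.validate()` reports all of these comparisons, pass or fail, and the
generated report prints the grid; nothing is tuned to hide the misses.

## 5. Sensitivity analyses

- **One-way (tornado).** Every registry parameter is set to its printed low
  and high bound with all others at base and the full ICER recomputed; the
  swing is |ICER_high − ICER_low|. The minimum ICER over all bounds
  (~47,929 USD/QALY) stays far above the 27,130 threshold.
- **Probabilistic.** Each sampled parameter gets a method-of-moments Beta
  (probabilities, utility) or Gamma (costs, durations, disutilities)
  distribution from its point estimate and range, with
  SD = (high − low)/3.92 (the range read as a 95% interval). Survival
  parameters and the discount rate are fixed across draws. Cohort traces do
  not depend on the sampled table, so each draw re-runs only the economics —
  1000 draws take well under a second. The CEAC is the fraction of draws
  with positive NMB over a 0–120,000 USD/QALY grid.

## 6. Synthetic patient-level data

`fruqcea.synthetic` generates pseudo individual-patient data from a known
Weibull with optional administrative censoring, estimates the Kaplan-Meier
curve (via lifelines), and `fit_weibull_km` recovers Weibull parameters by
regressing log(−log S) on log t. This is a testing and demonstration
harness — it shows the whole digitise-fit-simulate pathway is consistent —
not a re-digitisation of the trial curves.

## 7. Numerical notes

- Per-cycle probabilities use `-expm1(H(t) − H(t+1))` on cumulative hazards
  for accuracy in the tails.
- All randomness goes through `numpy.random.default_rng` with explicit seeds;
  every stochastic result records its seed.
- Property-based tests (hypothesis, derandomized) enforce cohort
  conservation, absorbing death, trace/survival telescoping to 10⁻¹⁰, and
  distribution moment round-trips.

## 8. Limitations

- The original fitted survival parameters and software conventions are
  unpublished; everything in §4 is inference, and the published incremental
  results are reproduced only to ~4–8%, not to rounding.
- Utilities and AE management costs come from external literature (as in the
  source analysis), not from trial EQ-5D data.
- Progression-free survival is not modelled separately; time on treatment is
  its proxy, as in the source analysis.
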