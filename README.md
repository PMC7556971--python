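# fruqcea

Markov cohort cost-effectiveness model of **fruquintinib plus best supportive
care (BSC) versus BSC alone** for third-line metastatic colorectal cancer,
from the perspective of the Chinese healthcare payer.

The model re-implements a published trial-based economic evaluation built on
the FRESCO randomized trial (median overall survival 9.3 vs 6.6 months,
hazard ratio 0.65). Because the original analysis did not publish its fitted
survival-curve parameters, this package ships a calibration module that
re-derives them from the published arm-level outputs, makes the residual
disagreement explicit, and treats the published totals as validation targets
rather than inputs.

## What the model does

- **Structure** — a cohort Markov model with 28-day cycles over a lifetime
  horizon. The fruquintinib arm has three states (*on treatment*, *off
  treatment / BSC*, *dead*); the BSC arm has two. Overall survival follows a
  Weibull curve per arm with the scale pinned to the trial median; treatment
  discontinuation is exponential (median 3.7 months).
- **Economics** — per-cycle drug and BSC costs, one-off grade ≥3
  adverse-event costs and QALY losses, utility 0.66 while alive, 3% annual
  discounting. Two pricing scenarios: the post-negotiation listed price
  (drug cost every treated cycle) and the pre-negotiation
  patient-assistance scheme (drug charged only in treated cycles 1, 2 and 5).
- **Outputs** — discounted cost and QALYs per arm, incremental
  cost-effectiveness ratio (ICER), net monetary benefit against a
  willingness-to-pay threshold of USD 27,130/QALY (3× per-capita GDP),
  one-way (tornado) sensitivity analysis, 1000-draw probabilistic
  sensitivity analysis with Beta/Gamma distributions, and the
  cost-effectiveness acceptability curve.

## Quick start

```python
from fruqcea import load_parameters, evaluate, run_psa

params = load_parameters()          # packaged registry + frozen calibration
ce = evaluate(params, "post_negotiation")
print(ce.intervention.cost)         # ~20,841 USD   (published: 20,750.9)
print(ce.intervention.qaly)         # ~0.6381 QALY  (published: 0.6404)
print(ce.comparator.cost)           # ~11,999 USD   (published: 12,042.2)
print(ce.icer)                      # ~55,715 USD/QALY

psa = run_psa(params, "post_negotiation", n=1000, seed=0)
print(psa.prob_cost_effective(27130.0))   # ~0.00 — not cost-effective
```

Narrative walk-throughs live in `examples/` (base case and validation,
sensitivity analyses, survival fitting on synthetic patient-level data).

A thin CLI wraps the same library calls:

```bash
fruqcea calibrate --out-dir outputs     # re-derive the Weibull shapes
fruqcea run --scenario post_negotiation --out-dir outputs
fruqcea report --seed 0 --out-dir outputs   # both scenarios + markdown report
```

## Repository layout

- `src/fruqcea/` — the library: `params` (registry + distributions),
  `survival` (Weibull/exponential curves, Kaplan-Meier fitting), `markov`
  (cohort engine), `economics` (discounted accrual, ICER/NMB), `model`
  (pipeline glue), `calibration` (shape search + validation grid),
  `sensitivity` (tornado, PSA, CEAC), `synthetic` (pseudo patient-level
  data), `report` and `cli`.
- `src/fruqcea/data/default_config.yaml` — the full parameter registry,
  structural constants, reference values and frozen calibration; any field
  can be overridden via `--config`.
- `tests/` — unit, property-based (hypothesis) and acceptance tests.
- `examples/`, `scripts/`, `docs/`.
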