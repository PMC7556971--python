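"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis sweeps each registry parameter across its printed
range with everything else at base; the probabilistic analysis samples all
Beta/Gamma distributions jointly and summarises decision uncertainty as a
cost-effectiveness acceptability curve (CEAC).

Run with:  python examples/02_sensitivity.py
"""

import numpy as np

from fruqcea import ceac, load_parameters, one_way_sa, run_psa, tornado_frame

params = load_parameters()  # ships with a frozen calibration block

# --- one-way sensitivity -------------------------------------------------
entries = one_way_sa(params, "post_negotiation")
print("Tornado (top 5 by ICER swing):")
print(tornado_frame(entries).head(5).to_string(index=False))

min_icer = min(min(e.icer_at_low, e.icer_at_high) for e in entries)
print(f"\nMinimum one-way ICER: {min_icer:,.1f} USD/QALY")
print(f"WTP threshold:        {params.constants.wtp_threshold:,.1f} USD/QALY")
print("=> no single-parameter excursion makes fruquintinib cost-effective.")

# --- probabilistic sensitivity -------------------------------------------
psa = run_psa(params, "post_negotiation", n=1000, seed=0)
print(f"\nPSA ({psa.n} draws, seed {psa.seed}):")
print(f"  mean incremental cost:   {np.mean(psa.incremental_cost):>10,.1f} USD")
print(f"  mean incremental effect: {np.mean(psa.incremental_effect):>10.4f} QALY")

print("\nCEAC landmarks:")
for wtp in (27130.0, 40000.0, 54000.0, 60000.0, 80000.0):
    print(f"  P(cost-effective @ {wtp:>7,.0f}) = {psa.prob_cost_effective(wtp):.3f}")

points = ceac(psa)
crossing = next((p.wtp for p in points if p.probability_cost_effective >= 0.5), None)
print(f"\nWTP at which P(cost-effective) first reaches 50%: {crossing:,.0f} USD/QALY")
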