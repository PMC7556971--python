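"""Scenario orchestration and human-readable reporting.

A scenario is one pricing regime (post- or pre-price-negotiation) pushed
through the whole pipeline: calibrated curves -> cohort traces -> economics ->
one-way SA -> PSA/CEAC -> validation. Both scenarios share the same cohort
traces and utilities, so their QALY outputs are identical by construction;
only the drug cost schedule differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .calibration import ValidationReport, validate
from .economics import CEResult, net_monetary_benefit
from .model import SCENARIOS, evaluate, run_traces
from .params import ParameterSet
from .sensitivity import (
    CEACPoint,
    PSAResult,
    TornadoEntry,
    ceac,
    ceac_frame,
    one_way_sa,
    run_psa,
    tornado_frame,
)

__all__ = ["ScenarioResult", "run_scenario", "render_report", "write_outputs"]


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    ce: CEResult
    tornado: list[TornadoEntry]
    psa: PSAResult | None
    ceac_points: list[CEACPoint] | None
    validation: ValidationReport


def run_scenario(
    params: ParameterSet,
    scenario: str = "post_negotiation",
    seed: int | None = None,
    n_psa: int = 1000,
) -> ScenarioResult:
    """Run the full pipeline for one pricing scenario; deterministic given seed.

    ``n_psa=0`` skips the Monte Carlo stage (the report marks it skipped).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r} (expected one of {SCENARIOS})")
    traces = run_traces(params)  # raises early, with guidance, if uncalibrated
    ce = evaluate(params, scenario, traces=traces)
    tornado = one_way_sa(params, scenario)
    psa = run_psa(params, scenario, n=n_psa, seed=seed) if n_psa > 0 else None
    points = ceac(psa) if psa is not None else None
    validation = validate(params)
    return ScenarioResult(scenario, ce, tornado, psa, points, validation)


def _fmt(x: float, nd: int = 1) -> str:
    return f"{x:,.{nd}f}"


def _scenario_table(res: ScenarioResult) -> list[str]:
    ce = res.ce
    return [
        f"### Scenario: {res.scenario}",
        "",
        "| Quantity | Fruquintinib | Placebo (BSC) |",
        "|---|---|---|",
        f"| Cost, USD | {_fmt(ce.intervention.cost)} | {_fmt(ce.comparator.cost)} |",
        f"| Effect, QALY | {ce.intervention.qaly:.4f} | {ce.comparator.qaly:.4f} |",
        f"| Incremental cost, USD | {_fmt(ce.incremental_cost)} | - |",
        f"| Incremental effect, QALY | {ce.incremental_effect:.5f} | - |",
        f"| ICER, USD/QALY | {_fmt(ce.icer)} | - |",
        "",
    ]


def render_report(results: list[ScenarioResult], wtp_threshold: float = 27130.0) -> str:
    """Markdown report: scenario tables, tornado, CEAC landmarks, validation grid."""
    lines = [
        "# Cost-effectiveness results: fruquintinib vs best supportive care",
        "",
        f"Willingness-to-pay threshold: USD {_fmt(wtp_threshold, 0)}/QALY "
        "(three times per-capita GDP).",
        "",
    ]
    for res in results:
        lines += _scenario_table(res)
        nmb = net_monetary_benefit(res.ce, wtp_threshold)
        verdict = "cost-effective" if nmb > 0 else "not cost-effective"
        lines += [
            f"Net monetary benefit at threshold: USD {_fmt(nmb)} ({verdict}).",
            "",
            "#### One-way sensitivity (top 10 by ICER swing)",
            "",
            "| Parameter | ICER at low | ICER at high | Swing |",
            "|---|---|---|---|",
        ]
        for e in res.tornado[:10]:
            lines.append(
                f"| {e.parameter} | {_fmt(e.icer_at_low)} | {_fmt(e.icer_at_high)} "
                f"| {_fmt(e.swing)} |"
            )
        lines.append("")
        if res.psa is None:
            lines += ["#### Probabilistic sensitivity analysis: skipped", ""]
        else:
            lines += [
                f"#### Probabilistic sensitivity analysis (n = {res.psa.n}, "
                f"seed = {res.psa.seed})",
                "",
                "| WTP, USD/QALY | P(cost-effective) |",
                "|---|---|",
            ]
            for w in (wtp_threshold, 40000.0, 49000.0, 54000.0, 60000.0):
                lines.append(f"| {_fmt(w, 0)} | {res.psa.prob_cost_effective(w):.3f} |")
            lines.append("")
    if results:
        lines += ["## Validation against published outputs", ""]
        df = results[0].validation.to_frame()
        lines += [
            "| Quantity | Model | Reference | Error | Pass |",
            "|---|---|---|---|---|",
        ]
        for _, row in df.iterrows():
            err = f"{row['error']:+.2%}" if row["kind"] == "relative" else f"{row['error']:+.3f}"
            lines.append(
                f"| {row['quantity']} | {row['model']:.4f} | {row['reference']:.4f} "
                f"| {err} | {'yes' if row['passed'] else 'NO'} |"
            )
        lines.append("")
    return "\n".join(lines)


def write_outputs(results: list[ScenarioResult], out_dir) -> None:
    """Persist all artifacts (CSV tables + markdown report) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for res in results:
        tag = res.scenario
        tornado_frame(res.tornado).to_csv(out / f"tornado_{tag}.csv", index=False)
        if res.psa is not None:
            res.psa.results.to_csv(out / f"psa_samples_{tag}.csv", index=False)
            ceac_frame(res.ceac_points).to_csv(out / f"ceac_{tag}.csv", index=False)
    if results:
        results[0].validation.to_frame().to_csv(out / "validation.csv", index=False)
    (out / "report.md").write_text(render_report(results))
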