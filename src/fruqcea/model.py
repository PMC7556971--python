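"""Pipeline glue: from a parameter registry to an incremental result.

Separating trace generation from economic accumulation lets the sensitivity
analyses reuse the (parameter-table-independent) cohort traces: nothing in
the varied table touches the survival curves, so deterministic and
probabilistic SA only re-run the economics.
"""

from __future__ import annotations

from typing import Mapping

from .economics import CEResult, CostSchedule, accumulate, ae_burden, compute_icer
from .markov import ModelSpec, StateTrace, run_cohort
from .params import ParameterSet
from .survival import ExponentialDuration, WeibullSurvival

__all__ = ["SCENARIOS", "build_spec", "run_arm_trace", "run_traces", "evaluate"]

SCENARIOS = ("post_negotiation", "pre_negotiation")


def _require_calibration(params: ParameterSet, arm: str) -> float:
    try:
        return params.calibrated_shapes[arm]
    except KeyError:
        raise ValueError(
            f"no calibrated Weibull shape for arm {arm!r}: run "
            "fruqcea.calibration.calibrate (CLI: `fruqcea calibrate`) or load a "
            "config with a calibration block"
        ) from None


def build_spec(params: ParameterSet, arm: str) -> ModelSpec:
    """Cohort specification for one arm from the frozen calibration."""
    shape = _require_calibration(params, arm)
    c, s = params.constants, params.settings
    if arm == "fruquintinib":
        curve = WeibullSurvival.from_median(c.median_os_fruq, shape)
        disc = ExponentialDuration(c.median_treatment_duration)
    else:
        curve = WeibullSurvival.from_median(c.median_os_placebo, shape)
        disc = None
    return ModelSpec(
        arm=arm,
        os_curve=curve,
        discontinuation=disc,
        cycle_length_days=c.cycle_length_days,
        max_cycles=s.max_cycles,
        stop_threshold=s.stop_threshold,
    )


def run_arm_trace(params: ParameterSet, arm: str) -> StateTrace:
    return run_cohort(build_spec(params, arm))


def run_traces(params: ParameterSet) -> dict[str, StateTrace]:
    return {arm: run_arm_trace(params, arm) for arm in ("fruquintinib", "placebo")}


def build_schedule(
    params: ParameterSet,
    arm: str,
    scenario: str = "post_negotiation",
    values: Mapping[str, float] | None = None,
) -> CostSchedule:
    """Cost schedule for one arm under a pricing scenario.

    ``values`` overrides parameter point estimates by name (sensitivity
    analyses); anything absent falls back to the base value.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r} (expected one of {SCENARIOS})")
    vals = dict(params.base_values())
    if values:
        vals.update(values)
    ae_cost, ae_qaly = ae_burden(params.ae_profiles(arm), vals)
    bsc_cost = vals["cost_bsc_per_cycle"]
    if arm == "placebo":
        return CostSchedule.bsc_only(bsc_cost, ae_cost, ae_qaly)
    concurrent = params.settings.concurrent_bsc_while_on_treatment
    if scenario == "post_negotiation":
        return CostSchedule.post_negotiation(
            vals["cost_fruquintinib_post"], bsc_cost, ae_cost, ae_qaly, concurrent
        )
    return CostSchedule.pre_negotiation(
        vals["cost_fruquintinib_pre"],
        bsc_cost,
        ae_cost,
        ae_qaly,
        params.settings.pre_negotiation_paid_cycles,
        concurrent,
    )


def evaluate(
    params: ParameterSet,
    scenario: str = "post_negotiation",
    values: Mapping[str, float] | None = None,
    traces: Mapping[str, StateTrace] | None = None,
) -> CEResult:
    """Full deterministic model evaluation: fruquintinib vs best supportive care.

    ``traces`` may carry precomputed cohort traces (they do not depend on the
    parameter table, only on the calibration), otherwise they are built here.
    """
    if traces is None:
        traces = run_traces(params)
    vals = dict(params.base_values())
    if values:
        vals.update(values)
    utility = vals["utility_baseline"]
    rate = vals["discount_rate_annual"]
    s = params.settings
    cost_timing = "half" if s.half_cycle_correction else s.cost_timing
    utility_timing = "half" if s.half_cycle_correction else s.utility_timing

    arm_results = {}
    for arm in ("fruquintinib", "placebo"):
        schedule = build_schedule(params, arm, scenario, vals)
        arm_results[arm] = accumulate(
            traces[arm], schedule, utility, rate, cost_timing, utility_timing
        )
    return compute_icer(arm_results["fruquintinib"], arm_results["placebo"])
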