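"""Calibration of the survival extrapolation and validation against published outputs.

The source trial's fitted Weibull overall-survival parameters were never
published; only the arm medians (9.3 / 6.6 months), the hazard ratio (0.65)
and the model's headline outputs are available. The per-arm Weibull *shape*
is therefore treated as a free calibration parameter: the scale is tied to
the arm's median OS, and the shape is chosen to minimise the squared relative
error of the arm's (discounted cost, discounted QALY) against the published
base-case values. This is declared openly as a calibration, not a re-fit of
the trial curves; the hazard ratio serves only as a cross-check diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model import evaluate, run_arm_trace
from .markov import median_survival_from_trace
from .params import ParameterSet
from .survival import WeibullSurvival, cycle_length_months

__all__ = ["CalibrationResult", "calibrate", "ValidationRow", "ValidationReport", "validate"]

#: maximum acceptable relative error per calibration target
CALIBRATION_TOLERANCE = 0.02


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the per-arm Weibull shape search."""

    shapes: dict[str, float]
    rel_errors: dict[str, float]  # per-target relative errors at the optimum
    objective: dict[str, float]  # per-arm summed squared relative error
    diagnostics: dict[str, float]
    tolerance: float
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """All targets within tolerance (failures are reported, never hidden)."""
        return all(abs(e) <= self.tolerance for e in self.rel_errors.values())


def _arm_targets(params: ParameterSet, arm: str) -> tuple[float, float]:
    r = params.reference
    if arm == "fruquintinib":
        return r.cost_fruq_post, r.qaly_fruq
    return r.cost_placebo, r.qaly_placebo


def _arm_result(params: ParameterSet, arm: str):
    """Single-arm (cost, QALY) under the post-negotiation scenario."""
    from .economics import accumulate
    from .model import build_schedule

    trace = run_arm_trace(params, arm)
    schedule = build_schedule(params, arm, "post_negotiation")
    vals = params.base_values()
    s = params.settings
    return accumulate(
        trace,
        schedule,
        vals["utility_baseline"],
        vals["discount_rate_annual"],
        "half" if s.half_cycle_correction else s.cost_timing,
        "half" if s.half_cycle_correction else s.utility_timing,
    )


def calibrate(
    params: ParameterSet,
    shape_bounds: tuple[float, float] = (0.8, 2.5),
    tolerance: float = CALIBRATION_TOLERANCE,
    xatol: float = 1e-8,
) -> CalibrationResult:
    """Search each arm's Weibull shape against the published arm cost and QALY.

    Deterministic (bounded scalar minimisation, no RNG). Returns the shapes
    plus per-target relative errors and verification diagnostics (simulated
    median OS per arm, implied cumulative-hazard ratio at 12 months). Targets
    whose error exceeds ``tolerance`` are flagged in ``messages`` -- the
    result still carries the optimum, but it must not be silently accepted.
    """
    shapes: dict[str, float] = {}
    rel_errors: dict[str, float] = {}
    objective: dict[str, float] = {}

    for arm in ("fruquintinib", "placebo"):
        target_cost, target_qaly = _arm_targets(params, arm)

        def obj(shape: float, arm=arm, tc=target_cost, tq=target_qaly) -> float:
            trial = params.with_calibration({arm: shape})
            res = _arm_result(trial, arm)
            return ((res.cost - tc) / tc) ** 2 + ((res.qaly - tq) / tq) ** 2

        opt = minimize_scalar(obj, bounds=shape_bounds, method="bounded", options={"xatol": xatol})
        shapes[arm] = float(opt.x)
        objective[arm] = float(opt.fun)

    calibrated = params.with_calibration(shapes)
    ce = evaluate(calibrated, "post_negotiation")
    rel_errors = {
        "cost_fruquintinib": (ce.intervention.cost - params.reference.cost_fruq_post)
        / params.reference.cost_fruq_post,
        "qaly_fruquintinib": (ce.intervention.qaly - params.reference.qaly_fruq)
        / params.reference.qaly_fruq,
        "cost_placebo": (ce.comparator.cost - params.reference.cost_placebo)
        / params.reference.cost_placebo,
        "qaly_placebo": (ce.comparator.qaly - params.reference.qaly_placebo)
        / params.reference.qaly_placebo,
    }

    c = params.constants
    curves = {
        "fruquintinib": WeibullSurvival.from_median(c.median_os_fruq, shapes["fruquintinib"]),
        "placebo": WeibullSurvival.from_median(c.median_os_placebo, shapes["placebo"]),
    }
    diagnostics = {
        "median_os_fruquintinib": median_survival_from_trace(
            run_arm_trace(calibrated, "fruquintinib")
        ),
        "median_os_placebo": median_survival_from_trace(run_arm_trace(calibrated, "placebo")),
        "implied_hr_12m": float(
            curves["fruquintinib"].cumulative_hazard(12.0)
            / curves["placebo"].cumulative_hazard(12.0)
        ),
    }

    messages = [
        f"calibration failure: {name} off by {err:+.2%} (tolerance {tolerance:.0%})"
        for name, err in rel_errors.items()
        if abs(err) > tolerance
    ]
    return CalibrationResult(
        shapes=shapes,
        rel_errors=rel_errors,
        objective=objective,
        diagnostics=diagnostics,
        tolerance=tolerance,
        messages=messages,
    )


@dataclass(frozen=True)
class ValidationRow:
    quantity: str
    model: float
    reference: float
    tolerance: float
    kind: str  # "relative" or "absolute"

    @property
    def error(self) -> float:
        if self.kind == "relative":
            return (self.model - self.reference) / self.reference
        return self.model - self.reference

    @property
    def passed(self) -> bool:
        return abs(self.error) <= self.tolerance


@dataclass(frozen=True)
class ValidationReport:
    """Model outputs compared against every published headline number."""

    rows: list[ValidationRow]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "quantity": r.quantity,
                    "model": r.model,
                    "reference": r.reference,
                    "error": r.error,
                    "tolerance": r.tolerance,
                    "kind": r.kind,
                    "passed": r.passed,
                }
                for r in self.rows
            ]
        )


def validate(params: ParameterSet, include_sa_floor: bool = True) -> ValidationReport:
    """Compare the frozen model against all published outputs, pass/fail per row.

    Reproduction of the increments is structurally limited (see docs): small
    anti-correlated arm-level errors compound in IC/IE, so some incremental
    rows can fail their 2% bands while every arm-level row passes. The report
    states this honestly rather than widening bands.
    """
    from .sensitivity import one_way_sa  # deferred import, sensitivity builds on model

    r = params.reference
    half_cycle_months = 0.5 * cycle_length_months(params.constants.cycle_length_days)

    post = evaluate(params, "post_negotiation")
    pre = evaluate(params, "pre_negotiation")
    med_f = median_survival_from_trace(run_arm_trace(params, "fruquintinib"))
    med_p = median_survival_from_trace(run_arm_trace(params, "placebo"))

    rows = [
        ValidationRow("cost_fruquintinib_post", post.intervention.cost, r.cost_fruq_post, 0.02, "relative"),
        ValidationRow("cost_placebo", post.comparator.cost, r.cost_placebo, 0.02, "relative"),
        ValidationRow("qaly_fruquintinib", post.intervention.qaly, r.qaly_fruq, 0.02, "relative"),
        ValidationRow("qaly_placebo", post.comparator.qaly, r.qaly_placebo, 0.02, "relative"),
        ValidationRow("incremental_cost_post", post.incremental_cost, r.incremental_cost_post, 0.02, "relative"),
        ValidationRow("incremental_effect", post.incremental_effect, r.incremental_effect, 0.02, "relative"),
        ValidationRow("icer_post", post.icer, r.icer_post, 0.02, "relative"),
        ValidationRow("cost_fruquintinib_pre", pre.intervention.cost, r.cost_fruq_pre, 0.02, "relative"),
        ValidationRow("incremental_cost_pre", pre.incremental_cost, r.incremental_cost_pre, 0.02, "relative"),
        ValidationRow("icer_pre", pre.icer, r.icer_pre, 0.02, "relative"),
        ValidationRow(
            "icer_relative_reduction",
            1.0 - post.icer / pre.icer,
            1.0 - r.icer_post / r.icer_pre,
            0.02,
            "absolute",
        ),
        ValidationRow("median_os_fruquintinib", med_f, params.constants.median_os_fruq, half_cycle_months, "absolute"),
        ValidationRow("median_os_placebo", med_p, params.constants.median_os_placebo, half_cycle_months, "absolute"),
    ]
    if include_sa_floor:
        entries = one_way_sa(params, "post_negotiation")
        min_icer = min(min(e.icer_at_low, e.icer_at_high) for e in entries)
        wtp = params.constants.wtp_threshold
        # floor check: min one-way ICER must stay above the WTP threshold
        rows.append(
            ValidationRow("one_way_min_icer_vs_wtp", min_icer, wtp, max(min_icer - wtp, 0.0), "absolute")
        )
    return ValidationReport(rows)
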