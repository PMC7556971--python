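"""Economic accumulation: discounted costs and QALYs from a cohort trace.

Accrual runs over completed cycles n = 1..T; treatment cycle n spans trace
rows n-1 -> n. Three accrual timings are supported for each quantity:

* ``start``: occupancy at the start of the cycle, discounted at row n-1;
* ``end``: occupancy at the end of the cycle (post transition), discounted at
  row n -- the cohort pays for each cycle it completes;
* ``half``: the mean of the two, discounted at n - 1/2 (the standard
  half-cycle correction).

The frozen defaults (costs 'end', utility 'start') are part of the model
calibration; see docs/methods.md.

Adverse-event burdens are one-off: incidence-weighted management costs and
duration-adjusted utility decrements applied once at model entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .markov import StateTrace
from .params import AEProfile

__all__ = [
    "CostSchedule",
    "ArmResult",
    "CEResult",
    "discount_factor",
    "ae_burden",
    "accumulate",
    "compute_icer",
    "net_monetary_benefit",
]

DAYS_PER_YEAR = 365.25
TIMINGS = ("start", "end", "half")


def discount_factor(cycle_index, annual_rate: float, cycle_length_days: float = 28.0):
    """Discount factor (1+r)^(-t * cycle_days/365.25); 1 at cycle 0 or r=0."""
    if annual_rate < 0:
        raise ValueError("annual discount rate must be >= 0")
    t = np.asarray(cycle_index, dtype=float)
    out = (1.0 + annual_rate) ** (-(t * cycle_length_days / DAYS_PER_YEAR))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CostSchedule:
    """Cost structure of one arm.

    ``drug_paid_cycles`` lists the (1-based) treatment cycles in which the
    per-cycle drug price is charged; None charges every cycle while on
    treatment (the post-negotiation constant price), the empty tuple charges
    none (BSC-only arm). Under the pre-negotiation donation scheme patients
    pay only in cycles 1, 2 and 5.
    """

    arm: str
    drug_cost_per_cycle: float = 0.0
    drug_paid_cycles: tuple[int, ...] | None = None
    bsc_cost_per_cycle: float = 0.0
    ae_one_off_cost: float = 0.0
    ae_one_off_qaly_loss: float = 0.0
    concurrent_bsc_while_on_treatment: bool = True

    def drug_cost(self, treatment_cycle: int) -> float:
        """Drug price charged in the given 1-based treatment cycle."""
        if treatment_cycle < 1 or self.drug_cost_per_cycle == 0.0:
            return 0.0
        if self.drug_paid_cycles is None or treatment_cycle in self.drug_paid_cycles:
            return self.drug_cost_per_cycle
        return 0.0

    @classmethod
    def post_negotiation(cls, drug_cost, bsc_cost, ae_cost, ae_qaly_loss, concurrent=True):
        return cls(
            arm="fruquintinib",
            drug_cost_per_cycle=drug_cost,
            drug_paid_cycles=None,
            bsc_cost_per_cycle=bsc_cost,
            ae_one_off_cost=ae_cost,
            ae_one_off_qaly_loss=ae_qaly_loss,
            concurrent_bsc_while_on_treatment=concurrent,
        )

    @classmethod
    def pre_negotiation(
        cls, drug_cost, bsc_cost, ae_cost, ae_qaly_loss, paid_cycles=(1, 2, 5), concurrent=True
    ):
        return cls(
            arm="fruquintinib",
            drug_cost_per_cycle=drug_cost,
            drug_paid_cycles=tuple(paid_cycles),
            bsc_cost_per_cycle=bsc_cost,
            ae_one_off_cost=ae_cost,
            ae_one_off_qaly_loss=ae_qaly_loss,
            concurrent_bsc_while_on_treatment=concurrent,
        )

    @classmethod
    def bsc_only(cls, bsc_cost, ae_cost, ae_qaly_loss=0.0):
        return cls(
            arm="placebo",
            drug_cost_per_cycle=0.0,
            drug_paid_cycles=(),
            bsc_cost_per_cycle=bsc_cost,
            ae_one_off_cost=ae_cost,
            ae_one_off_qaly_loss=ae_qaly_loss,
        )


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime cost (USD) and effectiveness (QALY) of one arm."""

    cost: float
    qaly: float


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of an intervention arm against a comparator."""

    intervention: ArmResult
    comparator: ArmResult
    incremental_cost: float
    incremental_effect: float
    icer: float  # NaN when undefined (see quadrant)
    quadrant: str  # "tradeoff", "dominant", "dominated", "indifferent"


def ae_burden(
    aes: Sequence[AEProfile], values: Mapping[str, float] | None = None
) -> tuple[float, float]:
    """One-off adverse-event burden of an arm at model entry.

    Returns (expected management cost in USD, expected QALY loss). Each AE
    contributes incidence * cost and incidence * disutility * duration/365.25.
    ``values`` optionally overrides parameter point estimates by name (used by
    the sensitivity analyses).
    """

    def val(p):
        return p.base if values is None else values.get(p.name, p.base)

    cost = 0.0
    qaly_loss = 0.0
    for ae in aes:
        p = val(ae.probability)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"AE {ae.name!r}: probability {p} outside [0,1]")
        cost += p * val(ae.cost)
        qaly_loss += p * val(ae.disutility_magnitude) * val(ae.duration_days) / DAYS_PER_YEAR
    return cost, qaly_loss


def _cycle_weights(occ: np.ndarray, timing: str) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy weight and discount-time per completed cycle n = 1..T."""
    n = np.arange(1, len(occ))
    if timing == "start":
        return occ[:-1], n - 1.0
    if timing == "end":
        return occ[1:], n.astype(float)
    if timing == "half":
        return 0.5 * (occ[:-1] + occ[1:]), n - 0.5
    raise ValueError(f"unknown accrual timing {timing!r} (expected one of {TIMINGS})")


def accumulate(
    trace: StateTrace,
    schedule: CostSchedule,
    utility: float,
    annual_discount_rate: float,
    cost_timing: str = "end",
    utility_timing: str = "start",
) -> ArmResult:
    """Discounted lifetime cost and QALYs of one arm.

    Per-cycle costs: the drug price on on-treatment occupancy, the BSC cost on
    all alive occupancy when ``concurrent_bsc_while_on_treatment`` (supportive
    care continues alongside the drug) else on BSC-state occupancy only.
    QALYs: alive occupancy x utility x cycle length in years. One-off AE
    burdens are added (cost) / subtracted (QALYs) undiscounted at entry.
    """
    if not (0.0 <= utility <= 1.0):
        raise ValueError(f"utility must lie in [0,1], got {utility}")
    if schedule.arm != trace.arm:
        raise ValueError(
            f"schedule arm {schedule.arm!r} does not match trace arm {trace.arm!r}"
        )

    dl = trace.cycle_length_days
    cycle_years = dl / DAYS_PER_YEAR

    # costs
    on_w, t_c = _cycle_weights(trace.on_treatment, cost_timing)
    bsc_occ = trace.alive if schedule.concurrent_bsc_while_on_treatment else trace.bsc
    bsc_w, _ = _cycle_weights(bsc_occ, cost_timing)
    df_c = discount_factor(t_c, annual_discount_rate, dl)
    drug = np.array([schedule.drug_cost(n) for n in range(1, trace.n_cycles)])
    cost = float(np.sum(df_c * (on_w * drug + bsc_w * schedule.bsc_cost_per_cycle)))
    cost += schedule.ae_one_off_cost

    # QALYs
    alive_w, t_u = _cycle_weights(trace.alive, utility_timing)
    df_u = discount_factor(t_u, annual_discount_rate, dl)
    qaly = float(np.sum(df_u * alive_w) * utility * cycle_years)
    qaly -= schedule.ae_one_off_qaly_loss

    return ArmResult(cost=cost, qaly=qaly)


def compute_icer(intervention: ArmResult, comparator: ArmResult) -> CEResult:
    """Incremental cost, effect, and ICER of intervention vs comparator.

    Degenerate quadrants are labelled rather than raised: a cheaper & more
    effective intervention is "dominant" (ICER undefined), a costlier & less
    effective one "dominated"; identical arms are "indifferent".
    """
    ic = intervention.cost - comparator.cost
    ie = intervention.qaly - comparator.qaly
    if ie > 0 and ic > 0 or ie < 0 and ic < 0:
        quadrant, icer = "tradeoff", ic / ie
    elif ie >= 0 and ic <= 0:
        quadrant = "indifferent" if ie == 0 and ic == 0 else "dominant"
        icer = math.nan
    else:
        quadrant, icer = "dominated", math.nan
    return CEResult(
        intervention=intervention,
        comparator=comparator,
        incremental_cost=ic,
        incremental_effect=ie,
        icer=icer,
        quadrant=quadrant,
    )


def net_monetary_benefit(ce: CEResult, wtp: float) -> float:
    """NMB = WTP * incremental effect - incremental cost (USD)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * ce.incremental_effect - ce.incremental_cost
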