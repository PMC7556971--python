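"""Deterministic and probabilistic sensitivity analysis, and the CEAC.

One-way SA re-evaluates the full incremental result at each parameter's low
and high bound (its printed range; most embody +/-20% of base) with all other
inputs at base. PSA draws every Beta/Gamma parameter independently by the
method of moments from (base, range), re-evaluates the model per draw
(n = 1000 by default), and the cost-effectiveness acceptability curve (CEAC)
reports the fraction of draws with positive net monetary benefit across a
willingness-to-pay grid. Survival parameters and the discount rate carry no
published uncertainty distribution and are held fixed in PSA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import evaluate, run_traces
from .params import ParameterSet

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "one_way_sa",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at a parameter's bounds, all else at base; sorted by swing."""

    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way_sa(params: ParameterSet, scenario: str = "post_negotiation") -> list[TornadoEntry]:
    """One-way deterministic SA over every parameter with a non-degenerate range.

    Returns entries sorted by decreasing ICER swing (tornado order).
    """
    traces = run_traces(params)
    entries = []
    for name in params.varied_names():
        p = params[name]
        icers = []
        for bound in (p.low, p.high):
            ce = evaluate(params, scenario, values={name: bound}, traces=traces)
            icers.append(ce.icer)
        entries.append(
            TornadoEntry(
                parameter=name,
                low=p.low,
                high=p.high,
                icer_at_low=icers[0],
                icer_at_high=icers[1],
            )
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "swing": e.swing,
            }
            for e in entries
        ]
    )


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo samples: drawn parameter vectors and resulting economics."""

    draws: pd.DataFrame  # one column per sampled parameter
    results: pd.DataFrame  # cost/qaly per arm, incremental cost/effect
    scenario: str
    seed: int | None

    @property
    def n(self) -> int:
        return len(self.results)

    @property
    def incremental_cost(self) -> np.ndarray:
        return self.results["incremental_cost"].to_numpy()

    @property
    def incremental_effect(self) -> np.ndarray:
        return self.results["incremental_effect"].to_numpy()

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of draws with positive net monetary benefit at ``wtp``."""
        nmb = wtp * self.incremental_effect - self.incremental_cost
        return float(np.mean(nmb > 0.0))


def run_psa(
    params: ParameterSet,
    scenario: str = "post_negotiation",
    n: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PSAResult:
    """Probabilistic sensitivity analysis with ``n`` independent draws.

    Reproducible under a fixed ``seed`` (or an explicit generator). Parameters
    without a Beta/Gamma distribution stay at base in every draw.
    """
    if n < 1:
        raise ValueError("need at least one PSA draw")
    if rng is None:
        rng = np.random.default_rng(seed)
    traces = run_traces(params)
    sampled = params.sampled_names()

    draw_cols = {name: params[name].sample(rng, size=n) for name in sampled}
    records = []
    for i in range(n):
        values = {name: float(draw_cols[name][i]) for name in sampled}
        ce = evaluate(params, scenario, values=values, traces=traces)
        records.append(
            {
                "cost_fruquintinib": ce.intervention.cost,
                "qaly_fruquintinib": ce.intervention.qaly,
                "cost_placebo": ce.comparator.cost,
                "qaly_placebo": ce.comparator.qaly,
                "incremental_cost": ce.incremental_cost,
                "incremental_effect": ce.incremental_effect,
            }
        )
    return PSAResult(
        draws=pd.DataFrame(draw_cols),
        results=pd.DataFrame(records),
        scenario=scenario,
        seed=seed,
    )


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    probability_cost_effective: float


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid 0..120,000 USD/QALY in 1,000-USD steps."""
    return np.arange(0.0, 120001.0, 1000.0)


def ceac(psa: PSAResult, wtp_grid=None) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if psa.n == 0:
        raise ValueError("empty PSA sample")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    ic = psa.incremental_cost
    ie = psa.incremental_effect
    points = []
    for w in np.asarray(wtp_grid, dtype=float):
        points.append(CEACPoint(float(w), float(np.mean(w * ie - ic > 0.0))))
    return points


def ceac_frame(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wtp": [p.wtp for p in points],
            "probability_cost_effective": [p.probability_cost_effective for p in points],
        }
    )
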