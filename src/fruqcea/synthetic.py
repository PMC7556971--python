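"""Synthetic (pseudo) individual-patient survival data.

No patient-level data from the source trial are available, so the
survival-fitting path is exercised on generated data with the same
statistical structure the analysis assumes: Weibull event times with the
stated arm medians, under administrative censoring at a fixed follow-up time
(no dropout process). Every dataset records its generating parameters, so it
can be regenerated bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import KMCurve

__all__ = ["PseudoIPD", "generate_pseudo_ipd", "km_from_ipd"]


@dataclass(frozen=True)
class PseudoIPD:
    """Pseudo individual-patient data: (time, event) pairs plus provenance."""

    time_months: np.ndarray
    event: np.ndarray  # 1 = death observed, 0 = administratively censored
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_months, dtype=float)
        e = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "event", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if np.any(t <= 0):
            raise ValueError("event/censoring times must be positive")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.time_months)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_csv(self, path) -> None:
        """Write (time_months, event) CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"time_months": self.time_months, "event": self.event}).to_csv(
            path, index=False
        )
        path.with_suffix(".meta.json").write_text(json.dumps(self.metadata, indent=1))

    @classmethod
    def from_csv(cls, path) -> "PseudoIPD":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(), meta)


def generate_pseudo_ipd(
    shape: float,
    scale: float,
    n: int,
    admin_censor_time: float = math.inf,
    seed: int | None = None,
) -> PseudoIPD:
    """Draw n Weibull(shape, scale) survival times with administrative censoring.

    Times beyond ``admin_censor_time`` (months) are recorded as censored at
    that time. Reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if shape <= 0 or scale <= 0:
        raise ValueError("shape and scale must be positive")
    if admin_censor_time <= 0:
        raise ValueError("administrative censoring time must be positive")
    rng = np.random.default_rng(seed)
    times = scale * rng.weibull(shape, size=n)
    event = (times <= admin_censor_time).astype(int)
    times = np.minimum(times, admin_censor_time)
    # guard against a zero draw (probability zero, but times must be positive)
    times = np.maximum(times, np.finfo(float).tiny)
    meta = {
        "shape": shape,
        "scale": scale,
        "n": n,
        "admin_censor_time": admin_censor_time,
        "seed": seed,
    }
    return PseudoIPD(times, event, meta)


def km_from_ipd(ipd: PseudoIPD) -> KMCurve:
    """Product-limit (Kaplan-Meier) estimate evaluated at the event times."""
    if ipd.n_events == 0:
        raise ValueError("cannot estimate a KM curve without any events")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time_months, ipd.event)
    event_times = np.unique(ipd.time_months[ipd.event == 1])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return KMCurve(event_times, surv)
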