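"""Parametric survival curves and their conversion to per-cycle probabilities.

The cohort model advances in 28-day cycles while survival parameters are
expressed in months, so a single day/month convention is fixed here:
one month = 30.4375 days (the mean Gregorian month). Overall survival is
extrapolated with a two-parameter Weibull, S(t) = exp(-(t/lambda)^k);
treatment duration is modelled as exponential (constant per-cycle
discontinuation probability), both over a lifetime horizon with no cure
fraction or hazard cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DAYS_PER_MONTH",
    "cycle_length_months",
    "WeibullSurvival",
    "ExponentialDuration",
    "KMCurve",
    "weibull_from_median",
    "fit_weibull_km",
    "cycle_death_prob",
    "discontinuation_prob",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # mean Gregorian month, 365.25 / 12


def cycle_length_months(cycle_length_days: float = 28.0) -> float:
    """Length of one model cycle in months (default 28 days = 0.9199 months)."""
    return cycle_length_days / DAYS_PER_MONTH


@dataclass(frozen=True)
class WeibullSurvival:
    """Weibull survival curve S(t) = exp(-(t/scale)^shape), t in months.

    ``shape`` > 1 gives an increasing hazard (mortality accelerating with
    time since entry), ``shape`` = 1 the exponential special case.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"Weibull shape and scale must be positive, got "
                f"shape={self.shape}, scale={self.scale}"
            )

    @classmethod
    def from_median(cls, median: float, shape: float) -> "WeibullSurvival":
        """Construct the curve with the given median survival (months).

        Inverts median = scale * (ln 2)^(1/shape).
        """
        if median <= 0:
            raise ValueError(f"median must be positive, got {median}")
        if shape <= 0:
            raise ValueError(f"shape must be positive, got {shape}")
        return cls(shape=shape, scale=median / np.log(2.0) ** (1.0 / shape))

    @property
    def median(self) -> float:
        """Median survival time in months."""
        return self.scale * np.log(2.0) ** (1.0 / self.shape)

    def survival(self, t):
        """S(t) for t in months (scalar or array); S(0) = 1."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be non-negative")
        out = np.exp(-((t / self.scale) ** self.shape))
        return float(out) if out.ndim == 0 else out

    def cumulative_hazard(self, t):
        """H(t) = (t/scale)^shape."""
        t = np.asarray(t, dtype=float)
        out = (t / self.scale) ** self.shape
        return float(out) if out.ndim == 0 else out

    def cycle_death_prob(self, cycle_index, cycle_length_days: float = 28.0):
        """Per-cycle death probability P(t) = 1 - S(t+1)/S(t).

        ``cycle_index`` is the 0-based cycle number (scalar or array); cycle
        boundaries sit at t*delta and (t+1)*delta with delta the cycle length
        in months.
        """
        t = np.asarray(cycle_index, dtype=float)
        if np.any(t < 0):
            raise ValueError("cycle index must be non-negative")
        delta = cycle_length_months(cycle_length_days)
        # 1 - S(t+1)/S(t) = 1 - exp(H(t) - H(t+1)), numerically stable in the tail
        h0 = self.cumulative_hazard(t * delta)
        h1 = self.cumulative_hazard((t + 1.0) * delta)
        out = -np.expm1(h0 - h1)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExponentialDuration:
    """Exponentially distributed duration with the given median (months).

    Memoryless: the per-cycle event probability is the same in every cycle.
    Used for time on treatment (discontinuation for progression, toxicity or
    intolerance pooled into a single exit process).
    """

    median: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be positive, got {self.median}")

    @property
    def rate(self) -> float:
        """Event rate per month, ln 2 / median."""
        return np.log(2.0) / self.median

    def per_cycle_prob(self, cycle_length_days: float = 28.0) -> float:
        """Constant per-cycle event probability 1 - exp(-rate * delta)."""
        delta = cycle_length_months(cycle_length_days)
        return float(-np.expm1(-self.rate * delta))


@dataclass(frozen=True)
class KMCurve:
    """A Kaplan-Meier curve as ordered (time, survival) coordinates."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", surv)
        if times.shape != surv.shape or times.ndim != 1:
            raise ValueError("times and survival must be 1-D arrays of equal length")
        if len(times) == 0:
            raise ValueError("empty KM curve")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(surv) > 0):
            raise ValueError("survival must be non-increasing")
        if surv[0] > 1.0 or np.any(surv < 0.0):
            raise ValueError("survival values must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.times, "survival": self.survival}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "KMCurve":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy())


def weibull_from_median(median: float, shape: float) -> WeibullSurvival:
    """Weibull curve with the given median (months) and shape."""
    return WeibullSurvival.from_median(median, shape)


def fit_weibull_km(km: KMCurve) -> WeibullSurvival:
    """Least-squares Weibull fit to a Kaplan-Meier curve.

    Uses the linearisation log(-log S(t)) = shape*log t - shape*log scale
    over points with 0 < S < 1 and t > 0. Points at exactly 0 or 1 carry no
    information under the transform and are dropped (with a logged count).
    """
    mask = (km.survival > 0.0) & (km.survival < 1.0) & (km.times > 0.0)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("fit_weibull_km: excluded %d point(s) with S in {0,1} or t=0", n_dropped)
    t = km.times[mask]
    s = km.survival[mask]
    if len(t) < 3:
        raise ValueError(
            f"need at least 3 usable KM points with 0 < S < 1, got {len(t)}"
        )
    y = np.log(-np.log(s))
    x = np.log(t)
    slope, intercept = np.polyfit(x, y, 1)
    shape = slope
    scale = np.exp(-intercept / shape)
    return WeibullSurvival(shape=float(shape), scale=float(scale))


def cycle_death_prob(curve: WeibullSurvival, cycle_index, cycle_length_days: float = 28.0):
    """Per-cycle death probability from an overall-survival curve."""
    return curve.cycle_death_prob(cycle_index, cycle_length_days)


def discontinuation_prob(duration: ExponentialDuration, cycle_length_days: float = 28.0) -> float:
    """Constant per-cycle treatment-discontinuation probability."""
    return duration.per_cycle_prob(cycle_length_days)
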