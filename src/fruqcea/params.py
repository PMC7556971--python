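"""Model input registry: the full parameter table with ranges and distributions.

Every input of the decision model lives here: grade 3/4 adverse-event (AE)
incidences per arm, one-off AE management costs, per-cycle drug and best
supportive care (BSC) costs, the baseline health-state utility, AE
disutilities and durations, and the annual discount rate, each with its
deterministic range and its probabilistic-sensitivity-analysis (PSA)
distribution family.

Distribution construction follows standard CEA practice: the printed range is
read as a central 95% interval, so SD = (high - low)/3.92, and Beta/Gamma
shapes are obtained by the method of moments from (mean, SD). Disutilities
are stored as positive magnitudes and subtracted downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "Parameter",
    "AEProfile",
    "StructuralConstants",
    "ModelSettings",
    "ReferenceValues",
    "ParameterSet",
    "beta_from_point_and_range",
    "gamma_from_point_and_range",
    "load_parameters",
    "REQUIRED_PARAMETERS",
]

#: Central-interval width in standard deviations when a (low, high) range is
#: interpreted as a 95% interval. Configurable per call (e.g. 4.0 for a
#: mean +/- 2 SD reading).
DEFAULT_RANGE_Z = 3.92

ARMS = ("fruquintinib", "placebo")
DISTRIBUTIONS = ("beta", "gamma", "fixed")

#: Names every configuration must define; the default registry carries one
#: entry per row of the model's parameter table.
REQUIRED_PARAMETERS = (
    "prob_hypertension_fruq",
    "prob_hand_foot_syndrome_fruq",
    "prob_diarrhea_fruq",
    "prob_platelet_count_decreased_fruq",
    "prob_hypertension_bsc",
    "cost_bsc_per_cycle",
    "cost_fruquintinib_post",
    "cost_fruquintinib_pre",
    "cost_hypertension",
    "cost_hand_foot_syndrome",
    "cost_diarrhea",
    "cost_platelet_count_decreased",
    "utility_baseline",
    "duration_hand_foot_syndrome",
    "duration_diarrhea",
    "duration_hypertension",
    "duration_platelet_count_decreased",
    "disutility_hand_foot_syndrome",
    "disutility_diarrhea",
    "disutility_hypertension",
    "disutility_platelet_count_decreased",
    "discount_rate_annual",
)


def beta_from_point_and_range(
    base: float, low: float, high: float, z: float = DEFAULT_RANGE_Z
) -> tuple[float, float]:
    """Method-of-moments Beta(alpha, beta) with mean ``base`` and SD = range/z.

    Raises ValueError when the implied variance is infeasible for a Beta
    (var >= mean*(1-mean)).
    """
    if not (0.0 < base < 1.0):
        raise ValueError(f"Beta mean must lie in (0,1), got {base}")
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    sd = (high - low) / z
    var = sd * sd
    if var >= base * (1.0 - base):
        raise ValueError(
            f"range [{low}, {high}] implies variance {var:.4g} >= "
            f"mean*(1-mean) = {base * (1 - base):.4g}: infeasible Beta"
        )
    alpha = base * (base * (1.0 - base) / var - 1.0)
    beta = alpha * (1.0 - base) / base
    return alpha, beta


def gamma_from_point_and_range(
    base: float, low: float, high: float, z: float = DEFAULT_RANGE_Z
) -> tuple[float, float]:
    """Method-of-moments Gamma(shape, scale) with mean ``base`` and SD = range/z."""
    if base <= 0:
        raise ValueError(f"Gamma mean must be positive, got {base}")
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    sd = (high - low) / z
    var = sd * sd
    return base * base / var, var / base


@dataclass(frozen=True)
class Parameter:
    """One model input: point estimate, deterministic range, PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"
    units: str = ""

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"parameter {self.name!r}: unknown distribution "
                f"{self.distribution!r} (expected one of {DISTRIBUTIONS})"
            )
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"parameter {self.name!r}: violated invariant low <= base <= high "
                f"({self.low} <= {self.base} <= {self.high})"
            )
        if self.distribution == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValueError(
                f"parameter {self.name!r}: violated invariant: Beta-distributed "
                f"values must lie in [0,1], got range [{self.low}, {self.high}]"
            )
        if self.distribution == "gamma" and self.low <= 0.0:
            raise ValueError(
                f"parameter {self.name!r}: violated invariant: Gamma-distributed "
                f"values need low > 0, got {self.low}"
            )

    @property
    def is_sampled(self) -> bool:
        return self.distribution in ("beta", "gamma") and self.low < self.high

    def distribution_params(self, z: float = DEFAULT_RANGE_Z) -> tuple[float, float]:
        if self.distribution == "beta":
            return beta_from_point_and_range(self.base, self.low, self.high, z)
        if self.distribution == "gamma":
            return gamma_from_point_and_range(self.base, self.low, self.high, z)
        raise ValueError(f"parameter {self.name!r} has no sampling distribution")

    def sample(self, rng: np.random.Generator, size=None, z: float = DEFAULT_RANGE_Z):
        """Draw from the PSA distribution (a point mass for fixed parameters)."""
        if not self.is_sampled:
            return self.base if size is None else np.full(size, self.base)
        a, b = self.distribution_params(z)
        if self.distribution == "beta":
            return rng.beta(a, b, size=size)
        return rng.gamma(a, b, size=size)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "base": self.base,
            "low": self.low,
            "high": self.high,
            "distribution": self.distribution,
            "units": self.units,
        }


@dataclass(frozen=True)
class AEProfile:
    """A grade 3/4 adverse event: incidence, one-off cost, disutility, duration."""

    name: str
    probability: Parameter
    cost: Parameter
    disutility_magnitude: Parameter
    duration_days: Parameter

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability.base <= 1.0):
            raise ValueError(f"AE {self.name!r}: probability outside [0,1]")
        if self.disutility_magnitude.base < 0:
            raise ValueError(f"AE {self.name!r}: disutility magnitude must be >= 0")


@dataclass(frozen=True)
class StructuralConstants:
    """Fixed structural inputs of the model (not varied in any SA)."""

    cycle_length_days: float = 28.0
    dosing_days_per_cycle: float = 21.0
    wtp_threshold: float = 27130.0  # 3x per-capita GDP, stored as given
    unit_drug_cost_post: float = 53.8  # USD per 5 mg, post price negotiation
    unit_drug_cost_pre: float = 162.3  # USD per 5 mg, before negotiation
    median_os_fruq: float = 9.3  # months, trial median OS, fruquintinib arm
    median_os_placebo: float = 6.6  # months, trial median OS, placebo/BSC arm
    os_hazard_ratio: float = 0.65  # trial OS hazard ratio (calibration cross-check)
    median_treatment_duration: float = 3.7  # months; trial median PFS as stand-in

    def __post_init__(self) -> None:
        if self.cycle_length_days != self.dosing_days_per_cycle + 7.0:
            raise ValueError(
                "cycle length must equal dosing days + 7 rest days, got "
                f"{self.cycle_length_days} vs {self.dosing_days_per_cycle} + 7"
            )


@dataclass(frozen=True)
class ModelSettings:
    """Simulation and accrual conventions.

    ``cost_timing='end'`` charges per-cycle costs on post-transition occupancy
    (each completed cycle is paid for); ``utility_timing='start'`` accrues
    utility for everyone alive at the start of a cycle. This pairing is part
    of the frozen calibration (see docs); both accept 'start' or 'end'.
    """

    max_cycles: int = 260
    stop_threshold: float = 1e-3
    cost_timing: str = "end"
    utility_timing: str = "start"
    concurrent_bsc_while_on_treatment: bool = True
    pre_negotiation_paid_cycles: tuple[int, ...] = (1, 2, 5)  # 1-based, donation scheme
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        for attr in ("cost_timing", "utility_timing"):
            if getattr(self, attr) not in ("start", "end"):
                raise ValueError(f"{attr} must be 'start' or 'end'")


@dataclass(frozen=True)
class ReferenceValues:
    """Published model outputs used as calibration targets and validation refs."""

    cost_fruq_post: float = 20750.9
    cost_placebo: float = 12042.2
    qaly_fruq: float = 0.6404
    qaly_placebo: float = 0.4776
    incremental_cost_post: float = 8708.7
    incremental_effect: float = 0.16275
    icer_post: float = 53508.7
    cost_fruq_pre: float = 23590.0
    incremental_cost_pre: float = 11547.8
    icer_pre: float = 70952.6


_AE_NAMES = ("hypertension", "hand_foot_syndrome", "diarrhea", "platelet_count_decreased")


@dataclass(frozen=True)
class ParameterSet:
    """Validated registry of every model input plus frozen calibration block."""

    parameters: Mapping[str, Parameter]
    constants: StructuralConstants = field(default_factory=StructuralConstants)
    settings: ModelSettings = field(default_factory=ModelSettings)
    reference: ReferenceValues = field(default_factory=ReferenceValues)
    #: frozen Weibull OS shape per arm (scale tied to the arm's median OS)
    calibrated_shapes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [n for n in REQUIRED_PARAMETERS if n not in self.parameters]
        if missing:
            raise ValueError(f"missing required parameter(s): {', '.join(missing)}")
        unknown = [n for n in self.parameters if n not in REQUIRED_PARAMETERS]
        if unknown:
            raise ValueError(f"unknown parameter name(s): {', '.join(unknown)}")
        for arm in self.calibrated_shapes:
            if arm not in ARMS:
                raise ValueError(f"unknown arm in calibration block: {arm!r}")

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def base_values(self) -> dict[str, float]:
        """Point estimates for every parameter, keyed by name."""
        return {n: p.base for n, p in self.parameters.items()}

    def sampled_names(self) -> list[str]:
        """Parameters drawn in PSA (those with a Beta/Gamma distribution)."""
        return [n for n, p in self.parameters.items() if p.is_sampled]

    def varied_names(self) -> list[str]:
        """Parameters varied in one-way SA (those with a non-degenerate range)."""
        return [n for n, p in self.parameters.items() if p.low < p.high]

    def ae_profiles(self, arm: str) -> list[AEProfile]:
        """Adverse-event profiles entering an arm's entry burden.

        The fruquintinib arm carries all four grade 3/4 AEs; the BSC arm only
        hypertension (the sole AE with a materially different incidence).
        """
        if arm == "fruquintinib":
            names, suffix = _AE_NAMES, "_fruq"
        elif arm == "placebo":
            names, suffix = ("hypertension",), "_bsc"
        else:
            raise ValueError(f"unknown arm {arm!r}")
        return [
            AEProfile(
                name=ae,
                probability=self.parameters[f"prob_{ae}{suffix}"],
                cost=self.parameters[f"cost_{ae}"],
                disutility_magnitude=self.parameters[f"disutility_{ae}"],
                duration_days=self.parameters[f"duration_{ae}"],
            )
            for ae in names
        ]

    def with_calibration(self, shapes: Mapping[str, float]) -> "ParameterSet":
        return replace(self, calibrated_shapes=dict(shapes))

    # ---------------------------------------------------------------- I/O

    def to_dict(self) -> dict:
        return {
            "parameters": [p.to_dict() for p in self.parameters.values()],
            "constants": vars(self.constants).copy(),
            "settings": {
                **{k: v for k, v in vars(self.settings).items()},
                "pre_negotiation_paid_cycles": list(
                    self.settings.pre_negotiation_paid_cycles
                ),
            },
            "reference": vars(self.reference).copy(),
            "calibration": dict(self.calibrated_shapes),
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        params = {}
        for row in data.get("parameters", []):
            p = Parameter(**row)
            if p.name in params:
                raise ValueError(f"duplicate parameter {p.name!r}")
            params[p.name] = p
        settings_raw = dict(data.get("settings", {}))
        if "pre_negotiation_paid_cycles" in settings_raw:
            settings_raw["pre_negotiation_paid_cycles"] = tuple(
                settings_raw["pre_negotiation_paid_cycles"]
            )
        return cls(
            parameters=params,
            constants=StructuralConstants(**data.get("constants", {})),
            settings=ModelSettings(**settings_raw),
            reference=ReferenceValues(**data.get("reference", {})),
            calibrated_shapes=dict(data.get("calibration", {})),
        )

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        path = Path(source)
        text = path.read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def default(cls) -> "ParameterSet":
        """The packaged default registry, including the frozen calibration."""
        ref = importlib.resources.files("fruqcea").joinpath("data/default_config.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))


def load_parameters(source=None) -> ParameterSet:
    """Load and validate a parameter registry.

    ``source`` may be None (packaged defaults), a path to a YAML config, or a
    dict with the same structure. Invalid entries raise ValueError naming the
    offending parameter and rule.
    """
    if source is None:
        return ParameterSet.default()
    if isinstance(source, Mapping):
        return ParameterSet.from_dict(source)
    return ParameterSet.from_yaml(source)
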