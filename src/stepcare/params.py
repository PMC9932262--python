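"""Disease-progression parameters and hazard-rate conversions.

The simulator works on a weekly clock, but the published inputs are stated on
other time scales: an annual all-cause death rate, per-episode remission /
deterioration probabilities, and per-episode recurrence/relapse probabilities.
This module holds the parameter container (:class:`DiseaseParams`), validates
it, converts every probability to a weekly hazard
(:class:`WeeklyHazards`), and reads/writes the YAML configuration mirroring
the parameter table field for field.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ContractError",
    "Health",
    "Care",
    "SEVERITIES",
    "TriangularWeeks",
    "DiseaseParams",
    "WeeklyHazards",
    "geometric_step_hazard",
    "annual_to_weekly_hazard",
]

SEVERITIES = ("mild", "moderate", "severe")


class ConfigError(ValueError):
    """Raised for invalid model configuration."""


class ContractError(RuntimeError):
    """Raised when an operation is applied to an agent in the wrong state."""


class Health(enum.IntEnum):
    """Health-related state: disease-free or one of three severity levels."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def severity_index(self) -> int:
        if self is Health.NONE:
            raise ValueError("disease-free state has no severity index")
        return int(self) - 1


class Care(enum.IntEnum):
    """Care-related state within a disease episode."""

    NOT_APPLICABLE = 0
    UNTREATED = 1
    IN_TREATMENT = 2
    DISCHARGED = 3


def geometric_step_hazard(prob: float, window_weeks: float) -> float:
    """Weekly hazard that compounds to ``prob`` over ``window_weeks`` weeks.

    Solves ``1 - (1 - h)**window_weeks == prob`` for ``h``, i.e. geometric
    (memoryless) spreading of a per-window probability over weekly Bernoulli
    draws.

    Parameters
    ----------
    prob:
        Probability over the whole window, in ``[0, 1)``.
    window_weeks:
        Positive window length in weeks.
    """
    if not 0.0 <= prob < 1.0:
        raise ConfigError(f"probability must be in [0, 1), got {prob!r}")
    if window_weeks <= 0:
        raise ConfigError(f"window must be positive, got {window_weeks!r}")
    return 1.0 - (1.0 - prob) ** (1.0 / window_weeks)


def annual_to_weekly_hazard(annual_prob: float) -> float:
    """Convert an annual probability to the equivalent weekly hazard.

    ``1 - (1 - annual_prob)**(1/52)``; compounding 52 weekly draws reproduces
    the annual probability exactly.
    """
    return geometric_step_hazard(annual_prob, 52.0)


@dataclass(frozen=True)
class TriangularWeeks:
    """Triangular(min, mode, max) duration in weeks."""

    minimum: float
    mode: float
    maximum: float

    def __post_init__(self) -> None:
        if not (0 < self.minimum <= self.mode <= self.maximum):
            raise ConfigError(
                f"triangular parameters must satisfy 0 < min <= mode <= max, "
                f"got ({self.minimum}, {self.mode}, {self.maximum})"
            )

    @property
    def mean(self) -> float:
        return (self.minimum + self.mode + self.maximum) / 3.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.minimum, self.mode, self.maximum)


def _triple(x: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ConfigError(f"expected a (mild, moderate, severe) triple, got {x!r}")
    return t  # type: ignore[return-value]


@dataclass
class DiseaseParams:
    """Parameters of the individual-level depression progression model.

    Defaults are the published point estimates for an adult population:
    point prevalence ``p`` = 7.7%, incident severity shares
    (29.4, 38.8, 31.8)%, per-episode deterioration probabilities
    mild->moderate 7% and moderate->severe 6% (severe has no higher state),
    per-episode recovery probabilities after treatment (79.3, 64.5, 54.9)%
    and without treatment (81.7, 74.7, 57.8)%, recurrence 33% after an
    untreated episode vs relapse 14% after a treated one, an all-cause death
    rate of 1,045.7 per 100,000 person-years, and Triangular(min, mode, max)
    treatment durations per severity.

    ``untreated_episode_weeks`` is the window over which the per-episode
    remission and deterioration probabilities are spread into weekly hazards
    (the source states the probabilities without a time scale; 26 weeks, the
    mode of the mild/moderate treatment duration, is the documented default).
    ``relapse_window_weeks`` / ``relapse_delay_weeks`` control recurrence
    timing: no risk for the first ``delay`` weeks after an episode ends
    (recurrence is defined as falling ill again more than six months later),
    then a weekly hazard over the remaining active weeks chosen so the
    per-episode probability is exact over the window.

    ``emergency_admission_hazard`` is the weekly probability that an
    *untreated severe* agent reaches crisis services (CRHTT / emergency
    inpatient admission) — the severe pathway's extra coupling channel.

    ``reoffer_weekly`` selects the service-offer policy: by default each
    episode receives exactly one coverage draw when it becomes symptomatic
    (so the coverage level is the fraction of episodes ever treated); when
    True, agents left untreated are re-offered entry every week.
    """

    n0: int = 5000
    horizon_weeks: int = 104
    prevalence_p: float = 0.077
    severity_props: tuple[float, float, float] = (0.294, 0.388, 0.318)
    s11: float = 0.07
    s21: float = 0.06
    recovery_treated: tuple[float, float, float] = (0.793, 0.645, 0.549)
    recovery_untreated: tuple[float, float, float] = (0.817, 0.747, 0.578)
    recurrence_untreated: float = 0.33
    relapse_treated: float = 0.14
    annual_death_rate: float = 0.010457
    treatment_duration: tuple[TriangularWeeks, TriangularWeeks, TriangularWeeks] = (
        TriangularWeeks(4, 26, 52),
        TriangularWeeks(4, 26, 56),
        TriangularWeeks(26, 52, 76),
    )
    untreated_episode_weeks: float = 26.0
    relapse_window_weeks: float = 52.0
    relapse_delay_weeks: float = 26.0
    emergency_admission_hazard: float = 0.10
    reoffer_weekly: bool = False

    def __post_init__(self) -> None:
        self.severity_props = _triple(self.severity_props)
        self.recovery_treated = _triple(self.recovery_treated)
        self.recovery_untreated = _triple(self.recovery_untreated)
        durations = []
        for d in self.treatment_duration:
            if isinstance(d, TriangularWeeks):
                durations.append(d)
            else:
                durations.append(TriangularWeeks(*d))
        self.treatment_duration = tuple(durations)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if int(self.n0) < 1:
            raise ConfigError(f"initial population size must be >= 1, got {self.n0}")
        if self.horizon_weeks < 1:
            raise ConfigError("horizon must be at least one week")
        if not 0.0 <= self.prevalence_p < 1.0:
            raise ConfigError(f"prevalence must be in [0, 1), got {self.prevalence_p}")
        if abs(sum(self.severity_props) - 1.0) > 1e-9:
            raise ConfigError(
                f"severity proportions must sum to 1, got {self.severity_props}"
            )
        probs = {
            "s11": self.s11,
            "s21": self.s21,
            "recurrence_untreated": self.recurrence_untreated,
            "relapse_treated": self.relapse_treated,
            "annual_death_rate": self.annual_death_rate,
            "emergency_admission_hazard": self.emergency_admission_hazard,
        }
        for i, name in enumerate(SEVERITIES):
            probs[f"recovery_treated[{name}]"] = self.recovery_treated[i]
            probs[f"recovery_untreated[{name}]"] = self.recovery_untreated[i]
            probs[f"severity_props[{name}]"] = self.severity_props[i]
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v}")
        if self.annual_death_rate >= 1.0:
            raise ConfigError("annual death rate must be < 1")
        if self.untreated_episode_weeks <= 0:
            raise ConfigError("untreated episode window must be positive")
        if self.relapse_window_weeks <= 0:
            raise ConfigError("relapse window must be positive")
        if not 0 <= self.relapse_delay_weeks < self.relapse_window_weeks:
            raise ConfigError(
                "relapse delay must be non-negative and shorter than the window"
            )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatment_duration"] = [list(t.as_tuple()) for t in self.treatment_duration]
        d["severity_props"] = list(self.severity_props)
        d["recovery_treated"] = list(self.recovery_treated)
        d["recovery_untreated"] = list(self.recovery_untreated)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DiseaseParams":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown disease parameters: {sorted(unknown)}")
        kwargs = dict(d)
        if "treatment_duration" in kwargs:
            kwargs["treatment_duration"] = tuple(
                TriangularWeeks(*t) for t in kwargs["treatment_duration"]
            )
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DiseaseParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class WeeklyHazards:
    """Per-week hazards derived from :class:`DiseaseParams`.

    ``remission``/``deterioration`` are indexed (mild, moderate, severe);
    the severe deterioration hazard is zero (no state above severe).
    """

    death: float
    remission: tuple[float, float, float]
    deterioration: tuple[float, float, float]
    relapse_treated: float
    relapse_untreated: float
    relapse_delay_weeks: float
    relapse_window_weeks: float
    emergency: float

    @classmethod
    def from_params(cls, params: DiseaseParams) -> "WeeklyHazards":
        w = params.untreated_episode_weeks
        active = params.relapse_window_weeks - params.relapse_delay_weeks
        return cls(
            death=annual_to_weekly_hazard(params.annual_death_rate),
            remission=tuple(
                geometric_step_hazard(r, w) for r in params.recovery_untreated
            ),
            deterioration=(
                geometric_step_hazard(params.s11, w),
                geometric_step_hazard(params.s21, w),
                0.0,
            ),
            relapse_treated=geometric_step_hazard(params.relapse_treated, active),
            relapse_untreated=geometric_step_hazard(params.recurrence_untreated, active),
            relapse_delay_weeks=params.relapse_delay_weeks,
            relapse_window_weeks=params.relapse_window_weeks,
            emergency=params.emergency_admission_hazard,
        )

    @staticmethod
    def zeroed(params: DiseaseParams) -> "WeeklyHazards":
        """All-zero hazards (useful for deterministic duration tests)."""
        return WeeklyHazards(
            death=0.0,
            remission=(0.0, 0.0, 0.0),
            deterioration=(0.0, 0.0, 0.0),
            relapse_treated=0.0,
            relapse_untreated=0.0,
            relapse_delay_weeks=params.relapse_delay_weeks,
            relapse_window_weeks=params.relapse_window_weeks,
            emergency=0.0,
        )
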