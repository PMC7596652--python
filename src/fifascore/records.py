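"""Domain types for wearable-derived frailty assessment.

A cohort is observed as one :class:`DailyRecord` per device-day, reduced to
one :class:`WeeklyProfile` per patient (mean over retained monitoring days),
and paired with an :class:`OutcomeRecord` carrying the binary in-hospital
mortality endpoint.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

__all__ = [
    "Parameter",
    "Direction",
    "DEFAULT_DIRECTIONS",
    "DailyRecord",
    "WeeklyProfile",
    "OutcomeRecord",
    "ValidationError",
]


class ValidationError(ValueError):
    """A record violated one of its structural invariants."""


class Direction(str, enum.Enum):
    """Whether larger predictor values indicate the event (death)."""

    positive = "positive"
    negative = "negative"

    def orient(self, x):
        """Return values on a scale where larger means more at-risk."""
        return x if self is Direction.positive else -x


class Parameter(str, enum.Enum):
    """The scoreable tracker parameters (one per daily-record field)."""

    hr_min = "hr_min"
    hr_max = "hr_max"
    stress_rest_min = "stress_rest_min"
    stress_high_min = "stress_high_min"
    stress_overall = "stress_overall"
    steps = "steps"
    distance_km = "distance_km"
    sleep_deep_min = "sleep_deep_min"
    sleep_light_min = "sleep_light_min"
    sleep_awake_min = "sleep_awake_min"
    sleep_total_min = "sleep_total_min"


#: Default risk direction per parameter: the sign of its observed
#: association with hospital mortality (higher heart rate and stress load
#: are adverse; more walking, more rest and deeper sleep are protective).
DEFAULT_DIRECTIONS: dict[Parameter, Direction] = {
    Parameter.hr_min: Direction.positive,
    Parameter.hr_max: Direction.positive,
    Parameter.stress_rest_min: Direction.negative,
    Parameter.stress_high_min: Direction.positive,
    Parameter.stress_overall: Direction.positive,
    Parameter.steps: Direction.negative,
    Parameter.distance_km: Direction.negative,
    Parameter.sleep_deep_min: Direction.negative,
    Parameter.sleep_light_min: Direction.positive,
    Parameter.sleep_awake_min: Direction.positive,
    Parameter.sleep_total_min: Direction.negative,
}


def _is_null(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class DailyRecord:
    """One device-day of wearable summaries for one patient.

    Every measurement field is nullable: a ``None`` marks a device gap for
    that quantity on that day. ``day_index`` is the 0-based chronological
    ordinal of the day within the patient's monitoring window.
    """

    patient_id: str
    day_index: int
    steps: float | None = None
    distance_km: float | None = None
    hr_min: float | None = None
    hr_max: float | None = None
    stress_overall: float | None = None
    stress_high_min: float | None = None
    stress_rest_min: float | None = None
    sleep_deep_min: float | None = None
    sleep_light_min: float | None = None
    sleep_awake_min: float | None = None
    sleep_total_min: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first violated rule."""
        if self.day_index < 0:
            raise ValidationError(
                f"{self.patient_id}: day_index must be >= 0, got {self.day_index}"
            )
        for f in fields(self):
            if f.name in ("patient_id", "day_index"):
                continue
            v = getattr(self, f.name)
            if _is_null(v):
                continue
            if v < 0:
                raise ValidationError(
                    f"{self.patient_id} day {self.day_index}: "
                    f"{f.name} must be >= 0, got {v}"
                )
        if not _is_null(self.stress_overall) and self.stress_overall > 100:
            raise ValidationError(
                f"{self.patient_id} day {self.day_index}: "
                f"stress_overall must lie in [0, 100], got {self.stress_overall}"
            )
        if (
            not _is_null(self.hr_min)
            and not _is_null(self.hr_max)
            and self.hr_min > self.hr_max
        ):
            raise ValidationError(
                f"{self.patient_id} day {self.day_index}: "
                f"hr_min <= hr_max violated ({self.hr_min} > {self.hr_max})"
            )
        if (
            not _is_null(self.sleep_deep_min)
            and not _is_null(self.sleep_light_min)
            and not _is_null(self.sleep_total_min)
            and self.sleep_deep_min + self.sleep_light_min > self.sleep_total_min + 1e-9
        ):
            raise ValidationError(
                f"{self.patient_id} day {self.day_index}: "
                "sleep_deep_min + sleep_light_min <= sleep_total_min violated"
            )
        if (
            not _is_null(self.stress_high_min)
            and not _is_null(self.stress_rest_min)
            and self.stress_high_min + self.stress_rest_min > 1440 + 1e-9
        ):
            raise ValidationError(
                f"{self.patient_id} day {self.day_index}: "
                "stress_high_min + stress_rest_min exceeds 1440 minutes"
            )

    def value(self, parameter: Parameter) -> float | None:
        return getattr(self, Parameter(parameter).value)


@dataclass
class WeeklyProfile:
    """Per-patient mean of each parameter over retained monitoring days."""

    patient_id: str
    n_days_used: int
    values: dict[Parameter, float | None] = field(default_factory=dict)

    def value(self, parameter: Parameter) -> float | None:
        return self.values.get(Parameter(parameter))


@dataclass
class OutcomeRecord:
    """Binary in-hospital all-cause mortality for one patient."""

    patient_id: str
    hospital_death: bool

    def __post_init__(self) -> None:
        if self.hospital_death not in (0, 1, True, False):
            raise ValidationError(
                f"{self.patient_id}: hospital_death must be 0/1, "
                f"got {self.hospital_death!r}"
            )
        self.hospital_death = bool(self.hospital_death)
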