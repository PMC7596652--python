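"""The fitness-tracker assisted frailty score.

Three wearable-derived categories — walking, heart rate and preprocedural
stress — each contribute one point when the patient's weekly mean breaches
that category's threshold in its risk direction (exceeding for positive
correlation with mortality, subceeding for negative). The 0-3 total maps
onto four frailty stages; moderate or severe counts as frail for the
binary prevalence definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .records import DEFAULT_DIRECTIONS, Direction, Parameter, WeeklyProfile
from .roc import ThresholdSpec, youden_threshold

__all__ = [
    "Stage",
    "Category",
    "FifaConfig",
    "FifaResult",
    "ScoringError",
    "DEFAULT_CATEGORY_MAP",
    "assign_fifa",
    "assign_fifa_frame",
    "derive_fifa_config",
    "prevalence",
]


class ScoringError(ValueError):
    """A weekly profile is missing a value the score needs."""


class Stage(enum.IntEnum):
    """Frailty stage, one per total score."""

    no_frailty = 0
    mild_frailty = 1
    moderate_frailty = 2
    severe_frailty = 3

    @classmethod
    def parse(cls, name) -> "Stage":
        if isinstance(name, (int, cls)):
            return cls(name)
        key = str(name).strip().lower()
        # "borderline" appears as a synonym for the 1-point stage
        aliases = {"borderline": "mild_frailty", "borderline_frailty": "mild_frailty"}
        key = aliases.get(key, key)
        if not key.endswith("_frailty") and key != "no_frailty":
            key = {"no": "no_frailty", "mild": "mild_frailty",
                   "moderate": "moderate_frailty", "severe": "severe_frailty"}.get(key, key)
        return cls[key]


class Category(str, enum.Enum):
    """The three scored categories."""

    walking = "walking"
    heart_rate = "heart_rate"
    stress = "stress"


#: Default category-to-parameter map: daily step count for walking,
#: maximum heart rate for heart rate, overall stress level for stress.
DEFAULT_CATEGORY_MAP: dict[Category, Parameter] = {
    Category.walking: Parameter.steps,
    Category.heart_rate: Parameter.hr_max,
    Category.stress: Parameter.stress_overall,
}


@dataclass
class FifaConfig:
    """Thresholds for the three scored categories."""

    thresholds: dict[Category, ThresholdSpec]

    def __post_init__(self) -> None:
        self.thresholds = {Category(k): v for k, v in self.thresholds.items()}
        if set(self.thresholds) != set(Category):
            raise ValueError("config must cover exactly the three categories")
        params = [t.parameter for t in self.thresholds.values()]
        if None in params or len(set(params)) != len(params):
            raise ValueError("each category must map to a distinct parameter")

    def parameter(self, category: Category) -> Parameter:
        return self.thresholds[Category(category)].parameter


@dataclass
class FifaResult:
    """Per-patient score: category points, total, stage, binary frailty."""

    patient_id: str
    points: dict[Category, int]
    total: int
    stage: Stage
    frail_binary: bool


def assign_fifa(profile: WeeklyProfile, config: FifaConfig) -> FifaResult:
    """Score one weekly profile against the configured thresholds.

    A category scores 1 iff the weekly mean strictly exceeds the cutoff
    (positive direction) or strictly subceeds it (negative direction);
    a value exactly at the cutoff scores 0.
    """
    points: dict[Category, int] = {}
    for cat, spec in config.thresholds.items():
        value = profile.value(spec.parameter)
        if value is None:
            raise ScoringError(
                f"patient {profile.patient_id}: missing weekly value for "
                f"{spec.parameter.value} (category {cat.value})"
            )
        points[cat] = int(spec.calls_event(value))
    total = sum(points.values())
    stage = Stage(total)
    return FifaResult(
        patient_id=profile.patient_id,
        points=points,
        total=total,
        stage=stage,
        frail_binary=stage in (Stage.moderate_frailty, Stage.severe_frailty),
    )


def assign_fifa_frame(weekly: pd.DataFrame, config: FifaConfig) -> pd.DataFrame:
    """Vectorised scoring of a weekly frame.

    Returns columns ``patient_id, point_walking, point_heart_rate,
    point_stress, total, stage, frail_binary``.
    """
    out = pd.DataFrame({"patient_id": weekly["patient_id"].astype(str)})
    for cat in Category:
        spec = config.thresholds[cat]
        col = weekly[spec.parameter.value]
        if col.isna().any():
            bad = weekly.loc[col.isna(), "patient_id"].tolist()
            raise ScoringError(
                f"missing weekly value for {spec.parameter.value} "
                f"(category {cat.value}) in patients {bad}"
            )
        if spec.direction is Direction.positive:
            out[f"point_{cat.value}"] = (col > spec.cutoff).astype(int).values
        else:
            out[f"point_{cat.value}"] = (col < spec.cutoff).astype(int).values
    out["total"] = sum(out[f"point_{c.value}"] for c in Category)
    out["stage"] = out["total"].map(lambda t: Stage(t).name)
    out["frail_binary"] = out["total"] >= Stage.moderate_frailty
    return out


def derive_fifa_config(
    profiles,
    outcomes,
    category_map: dict[Category, Parameter] | None = None,
    directions: dict[Category, Direction] | None = None,
) -> FifaConfig:
    """Fit the three category thresholds by Youden-index maximisation.

    ``profiles`` may be a weekly DataFrame or a list of
    :class:`~fifascore.records.WeeklyProfile`; ``outcomes`` a DataFrame
    with ``patient_id, hospital_death`` or a list of outcome records.
    Each category's direction defaults to its parameter's known
    association direction with mortality.
    """
    weekly = _as_weekly_frame(profiles)
    out = _as_outcome_frame(outcomes)
    category_map = {
        Category(c): Parameter(p)
        for c, p in (category_map or DEFAULT_CATEGORY_MAP).items()
    }
    merged = weekly.merge(out, on="patient_id", how="inner")
    thresholds: dict[Category, ThresholdSpec] = {}
    for cat, param in category_map.items():
        direction = (directions or {}).get(cat, DEFAULT_DIRECTIONS[param])
        sub = merged[[param.value, "hospital_death"]].dropna(subset=[param.value])
        thresholds[cat] = youden_threshold(
            sub[param.value].to_numpy(float),
            sub["hospital_death"].to_numpy(bool),
            direction,
            parameter=param,
        )
    return FifaConfig(thresholds=thresholds)


def prevalence(results) -> float:
    """Fraction of patients classed frail (moderate or severe stage)."""
    if isinstance(results, pd.DataFrame):
        flags = results["frail_binary"].astype(bool)
        n = len(flags)
        frail = int(flags.sum())
    else:
        results = list(results)
        n = len(results)
        frail = sum(bool(r.frail_binary) for r in results)
    if n == 0:
        raise ValueError("prevalence undefined on an empty cohort")
    return frail / n


def _as_weekly_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        df = profiles.copy()
        df["patient_id"] = df["patient_id"].astype(str)
        return df
    from .aggregate import frame_from_profiles

    return frame_from_profiles(profiles)


def _as_outcome_frame(outcomes) -> pd.DataFrame:
    if isinstance(outcomes, pd.DataFrame):
        df = outcomes.copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df["hospital_death"] = df["hospital_death"].astype(bool)
        return df[["patient_id", "hospital_death"]]
    return pd.DataFrame(
        {
            "patient_id": [str(o.patient_id) for o in outcomes],
            "hospital_death": [bool(o.hospital_death) for o in outcomes],
        }
    )
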