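"""Conventional frailty comparators: the Edmonton Frail Scale category
and the 6-minute-walk-test gait-speed category.

Both are banded classifications with a binary frailty dichotomisation:
EFS counts mild frailty and worse as frail; the gait-speed comparator
counts anything but a normal walking speed (including an infeasible
test) as frail. Ordinal codes increase with frailty so both enter ROC
analysis with the positive direction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EfsCategory",
    "GaitCategory",
    "EfsAssessment",
    "GaitAssessment",
    "efs_classify",
    "gait_classify",
    "classify_comparators",
    "SIX_MWT_SECONDS",
]

#: Fixed duration of the 6-minute walk test.
SIX_MWT_SECONDS = 360.0


class EfsCategory(enum.IntEnum):
    """Edmonton Frail Scale bands, ordinal code = increasing frailty."""

    not_frail = 0       # 0-5 points
    vulnerable = 1      # 6-7 points
    mild = 2            # 8-9 points
    moderate = 3        # 10-11 points
    severe = 4          # >= 12 points


class GaitCategory(enum.IntEnum):
    """Gait-speed bands from the 6-minute walk test."""

    normal = 0          # > 0.83 m/s
    slow = 1            # 0.5 <= v <= 0.83 m/s
    very_slow = 2       # < 0.5 m/s
    not_feasible = 3    # test impossible (weakness, bedridden, pain)


@dataclass
class EfsAssessment:
    patient_id: str
    efs_points: int
    category: EfsCategory
    frail_binary: bool


@dataclass
class GaitAssessment:
    patient_id: str
    feasible: bool
    distance_m: float | None
    speed_mps: float | None
    category: GaitCategory
    frail_binary: bool


def efs_classify(efs_points: int, patient_id: str = "") -> EfsAssessment:
    """Band an Edmonton Frail Scale total (0-17 points).

    12 points is classed severe: the bands run 0-5, 6-7, 8-9, 10-11 and
    >=12, a gapless partition of the 0-17 range. Frail means mild
    frailty or worse.
    """
    points = int(efs_points)
    if points != efs_points or not 0 <= points <= 17:
        raise ValueError(f"EFS points must be an integer in [0, 17], got {efs_points!r}")
    if points <= 5:
        category = EfsCategory.not_frail
    elif points <= 7:
        category = EfsCategory.vulnerable
    elif points <= 9:
        category = EfsCategory.mild
    elif points <= 11:
        category = EfsCategory.moderate
    else:
        category = EfsCategory.severe
    return EfsAssessment(
        patient_id=str(patient_id),
        efs_points=points,
        category=category,
        frail_binary=category >= EfsCategory.mild,
    )


def gait_classify(
    feasible: bool, distance_m: float | None, patient_id: str = ""
) -> GaitAssessment:
    """Band a 6-minute-walk result by gait speed (distance / 360 s).

    Very slow below 0.5 m/s, slow in [0.5, 0.83], normal above 0.83; an
    infeasible test is its own (frail) category. Frail means any
    category other than normal.
    """
    if not feasible:
        return GaitAssessment(
            patient_id=str(patient_id),
            feasible=False,
            distance_m=None,
            speed_mps=None,
            category=GaitCategory.not_feasible,
            frail_binary=True,
        )
    if distance_m is None or pd.isna(distance_m):
        raise ValueError(f"patient {patient_id!r}: feasible 6MWT requires a distance")
    if distance_m < 0:
        raise ValueError(f"patient {patient_id!r}: distance_m must be >= 0")
    speed = float(distance_m) / SIX_MWT_SECONDS
    if speed < 0.5:
        category = GaitCategory.very_slow
    elif speed <= 0.83:
        category = GaitCategory.slow
    else:
        category = GaitCategory.normal
    return GaitAssessment(
        patient_id=str(patient_id),
        feasible=True,
        distance_m=float(distance_m),
        speed_mps=speed,
        category=category,
        frail_binary=category is not GaitCategory.normal,
    )


def classify_comparators(
    comparators: pd.DataFrame,
) -> tuple[list[EfsAssessment], list[GaitAssessment]]:
    """Classify a comparator table (patient_id, efs_points, gait_feasible,
    gait_distance_m) into both comparator assessments."""
    efs, gait = [], []
    for row in comparators.itertuples(index=False):
        efs.append(efs_classify(row.efs_points, patient_id=row.patient_id))
        dist = None if pd.isna(row.gait_distance_m) else float(row.gait_distance_m)
        gait.append(
            gait_classify(bool(row.gait_feasible), dist, patient_id=row.patient_id)
        )
    return efs, gait
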