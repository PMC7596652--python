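"""CSV readers and writers for the cohort file formats.

Three tables make up a cohort on disk: the daily tracker table (one row
per patient-day), the outcome table (one row per patient) and the
comparator table (Edmonton Frail Scale points and 6-minute-walk data).
Empty cells are nulls; encoding is UTF-8 with ``.`` as decimal separator.
Extra columns (further tracker channels the score does not use) are
tolerated and passed through by the frame readers.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import frame_from_profiles, profiles_from_frame
from .records import DailyRecord, OutcomeRecord, Parameter, WeeklyProfile

__all__ = [
    "DAILY_COLUMNS",
    "OUTCOME_COLUMNS",
    "WEEKLY_COLUMNS",
    "COMPARATOR_COLUMNS",
    "SchemaError",
    "read_daily_csv",
    "write_daily_csv",
    "read_daily_frame",
    "write_daily_frame",
    "read_outcomes_csv",
    "write_outcomes_csv",
    "read_weekly_csv",
    "write_weekly_csv",
    "read_comparators_csv",
    "write_comparators_csv",
]

_PARAM_COLS = [p.value for p in Parameter]
DAILY_COLUMNS = ["patient_id", "day_index", *_PARAM_COLS]
OUTCOME_COLUMNS = ["patient_id", "hospital_death"]
WEEKLY_COLUMNS = ["patient_id", "n_days_used", *_PARAM_COLS]
COMPARATOR_COLUMNS = ["patient_id", "efs_points", "gait_feasible", "gait_distance_m"]


class SchemaError(ValueError):
    """A CSV header is missing a mandatory column."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_daily_frame(path) -> pd.DataFrame:
    """Daily table as a DataFrame, sorted by (patient_id, day_index)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, DAILY_COLUMNS, path)
    df["patient_id"] = df["patient_id"].astype(str)
    return df.sort_values(["patient_id", "day_index"], kind="stable").reset_index(
        drop=True
    )


def read_daily_csv(path) -> list[DailyRecord]:
    """Daily table as validated records (extra columns are dropped)."""
    df = read_daily_frame(path)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        kwargs = {
            c: (None if pd.isna(getattr(row, c)) else float(getattr(row, c)))
            for c in _PARAM_COLS
        }
        try:
            records.append(
                DailyRecord(
                    patient_id=str(row.patient_id),
                    day_index=int(row.day_index),
                    **kwargs,
                )
            )
        except ValueError as exc:
            raise type(exc)(f"{path} row {i}: {exc}") from None
    return records


def write_daily_frame(daily: pd.DataFrame, path) -> None:
    cols = DAILY_COLUMNS + [c for c in daily.columns if c not in DAILY_COLUMNS]
    daily[cols].to_csv(path, index=False)


def write_daily_csv(records: Iterable[DailyRecord], path) -> None:
    rows = [
        {"patient_id": r.patient_id, "day_index": r.day_index}
        | {c: getattr(r, c) for c in _PARAM_COLS}
        for r in records
    ]
    pd.DataFrame(rows, columns=DAILY_COLUMNS).to_csv(path, index=False)


def read_outcomes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, OUTCOME_COLUMNS, path)
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient_id(s) {dup}")
    bad = ~df["hospital_death"].isin([0, 1])
    if bad.any():
        raise ValueError(f"{path}: hospital_death must be 0/1 (rows {list(df.index[bad])})")
    df["hospital_death"] = df["hospital_death"].astype(bool)
    return df[OUTCOME_COLUMNS]


def outcome_records(outcomes: pd.DataFrame) -> list[OutcomeRecord]:
    return [
        OutcomeRecord(str(r.patient_id), bool(r.hospital_death))
        for r in outcomes.itertuples(index=False)
    ]


def write_outcomes_csv(outcomes: pd.DataFrame, path) -> None:
    out = outcomes[OUTCOME_COLUMNS].copy()
    out["hospital_death"] = out["hospital_death"].astype(int)
    out.to_csv(path, index=False)


def read_weekly_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, WEEKLY_COLUMNS, path)
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_weekly_profiles(path) -> list[WeeklyProfile]:
    return profiles_from_frame(read_weekly_csv(path))


def write_weekly_csv(weekly, path) -> None:
    if not isinstance(weekly, pd.DataFrame):
        weekly = frame_from_profiles(weekly)
    weekly[WEEKLY_COLUMNS].to_csv(path, index=False)


def read_comparators_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, COMPARATOR_COLUMNS, path)
    df["patient_id"] = df["patient_id"].astype(str)
    df["gait_feasible"] = df["gait_feasible"].astype(bool)
    return df


def write_comparators_csv(comparators: pd.DataFrame, path) -> None:
    out = comparators[COMPARATOR_COLUMNS].copy()
    out["gait_feasible"] = out["gait_feasible"].astype(int)
    out.to_csv(path, index=False)
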