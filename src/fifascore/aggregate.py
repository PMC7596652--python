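"""Daily-to-weekly reduction of wearable records.

The first and the last monitoring day of each patient carry incomplete
activity data (the device is fitted mid-day and removed on admission), so
both are dropped by ordinal position before averaging. Remaining days are
averaged per parameter, ignoring nulls; patients left with fewer than
``min_days`` retained days are excluded and reported via a warning.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import pandas as pd

from .records import DailyRecord, Parameter, WeeklyProfile

__all__ = ["aggregate_weekly", "aggregate_weekly_frame", "MIN_DAYS_DEFAULT"]

#: Minimum retained monitoring days for a usable weekly profile. One week
#: of wear yields 7 retained days; 3 keeps short-compliance patients
#: usable while ruling out single-day profiles.
MIN_DAYS_DEFAULT = 3

_PARAM_COLS = [p.value for p in Parameter]


def aggregate_weekly_frame(
    daily: pd.DataFrame, min_days: int = MIN_DAYS_DEFAULT
) -> tuple[pd.DataFrame, list[str]]:
    """Trim-and-average a daily frame into one row per patient.

    Returns the weekly frame (columns ``patient_id``, ``n_days_used``, one
    per parameter) and the list of excluded patient ids.
    """
    if daily.empty:
        cols = ["patient_id", "n_days_used", *_PARAM_COLS]
        return pd.DataFrame(columns=cols), []
    df = daily.sort_values(["patient_id", "day_index"], kind="stable")
    g = df.groupby("patient_id", sort=True)["day_index"]
    first = g.transform("min")
    last = g.transform("max")
    retained = df[(df["day_index"] != first) & (df["day_index"] != last)]
    counts = df.groupby("patient_id", sort=True).size()
    kept_counts = (
        retained.groupby("patient_id", sort=True).size()
        if not retained.empty
        else pd.Series(dtype=int)
    )
    n_days = kept_counts.reindex(counts.index, fill_value=0)
    excluded = list(n_days.index[n_days < min_days])
    if excluded:
        msg = (
            f"{len(excluded)} patient(s) excluded with fewer than "
            f"{min_days} retained monitoring days: {excluded}"
        )
        if len(excluded) == len(counts):
            msg = "all patients excluded — " + msg
        warnings.warn(msg, stacklevel=2)
    keep = n_days.index[n_days >= min_days]
    retained = retained[retained["patient_id"].isin(keep)]
    if retained.empty:
        cols = ["patient_id", "n_days_used", *_PARAM_COLS]
        return pd.DataFrame(columns=cols), excluded
    means = retained.groupby("patient_id", sort=True)[_PARAM_COLS].mean()
    weekly = means.reset_index()
    weekly.insert(1, "n_days_used", n_days.loc[weekly["patient_id"]].values)
    return weekly, excluded


def aggregate_weekly(
    records: Iterable[DailyRecord], min_days: int = MIN_DAYS_DEFAULT
) -> list[WeeklyProfile]:
    """Record-level counterpart of :func:`aggregate_weekly_frame`."""
    rows = [
        {"patient_id": r.patient_id, "day_index": r.day_index}
        | {c: getattr(r, c) for c in _PARAM_COLS}
        for r in records
    ]
    daily = pd.DataFrame(rows, columns=["patient_id", "day_index", *_PARAM_COLS])
    weekly, _ = aggregate_weekly_frame(daily, min_days)
    return profiles_from_frame(weekly)


def profiles_from_frame(weekly: pd.DataFrame) -> list[WeeklyProfile]:
    out = []
    for row in weekly.itertuples(index=False):
        vals = {
            p: (None if pd.isna(getattr(row, p.value)) else float(getattr(row, p.value)))
            for p in Parameter
        }
        out.append(
            WeeklyProfile(
                patient_id=str(row.patient_id),
                n_days_used=int(row.n_days_used),
                values=vals,
            )
        )
    return out


def frame_from_profiles(profiles: Iterable[WeeklyProfile]) -> pd.DataFrame:
    rows = [
        {"patient_id": p.patient_id, "n_days_used": p.n_days_used}
        | {c.value: p.values.get(c) for c in Parameter}
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["patient_id", "n_days_used", *_PARAM_COLS])
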