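"""Head-to-head predictive comparison against hospital mortality.

``parameter_screen`` discriminates every tracker parameter on its own
(one ROC per channel, in its known risk direction); ``compare_scores``
pits the composite frailty instruments — the tracker score, the Edmonton
Frail Scale category and the gait-speed category — against each other
using their ordinal stage codes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .records import DEFAULT_DIRECTIONS, Direction, Parameter
from .roc import RocAnalysis, auc_rank
from .scoring import _as_outcome_frame, _as_weekly_frame

__all__ = ["parameter_screen", "compare_scores", "render_screen_table"]


def parameter_screen(
    profiles,
    outcomes,
    directions: dict[Parameter, Direction] | None = None,
    *,
    ci_method: str = "hanley-mcneil",
) -> pd.DataFrame:
    """One ROC analysis per tracker parameter, descending by AUC.

    Patients with a null weekly mean for a given parameter are dropped
    from that parameter's row only. Returns a frame with columns
    ``parameter, direction, auc, ci_low, ci_high, n_cases, n_controls``.
    """
    weekly = _as_weekly_frame(profiles)
    out = _as_outcome_frame(outcomes)
    merged = weekly.merge(out, on="patient_id", how="inner")
    rows = []
    for param in Parameter:
        direction = (directions or {}).get(param, DEFAULT_DIRECTIONS[param])
        sub = merged[[param.value, "hospital_death"]].dropna(subset=[param.value])
        roc = auc_rank(
            sub[param.value].to_numpy(float),
            sub["hospital_death"].to_numpy(bool),
            direction,
            ci_method=ci_method,
        )
        rows.append(
            {
                "parameter": param.value,
                "direction": direction.value,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "n_cases": roc.n_cases,
                "n_controls": roc.n_controls,
            }
        )
    table = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def _ordinal_frame(name, ids, codes, prevalence):
    return pd.DataFrame({"patient_id": [str(i) for i in ids], name: codes}), prevalence


def compare_scores(
    fifa,
    efs=None,
    gait=None,
    outcomes=None,
    *,
    ci_method: str = "hanley-mcneil",
) -> pd.DataFrame:
    """Compare frailty instruments as predictors of hospital mortality.

    ``fifa`` is a scores frame (from :func:`fifascore.scoring.assign_fifa_frame`)
    or a list of per-patient score results; ``efs`` and ``gait`` are
    optional lists of comparator assessments. Instruments enter the ROC
    as ordinal codes ordered by increasing frailty, direction positive.
    Patients are inner-joined on id; mismatches are reported via a
    warning. Returns one row per instrument with AUC, CI, counts and the
    instrument's binary frailty prevalence.
    """
    if outcomes is None:
        raise ValueError("outcomes are required")
    out = _as_outcome_frame(outcomes)

    tables: dict[str, tuple[pd.DataFrame, float]] = {}
    if isinstance(fifa, pd.DataFrame):
        tables["FIFA"] = _ordinal_frame(
            "code",
            fifa["patient_id"],
            fifa["total"].to_numpy(int),
            float(fifa["frail_binary"].astype(bool).mean()),
        )
    else:
        fifa = list(fifa)
        tables["FIFA"] = _ordinal_frame(
            "code",
            [r.patient_id for r in fifa],
            [int(r.total) for r in fifa],
            float(np.mean([r.frail_binary for r in fifa])),
        )
    if efs is not None:
        efs = list(efs)
        tables["EFS-C"] = _ordinal_frame(
            "code",
            [a.patient_id for a in efs],
            [int(a.category) for a in efs],
            float(np.mean([a.frail_binary for a in efs])),
        )
    if gait is not None:
        gait = list(gait)
        tables["GSC-6MWT"] = _ordinal_frame(
            "code",
            [a.patient_id for a in gait],
            [int(a.category) for a in gait],
            float(np.mean([a.frail_binary for a in gait])),
        )

    rows = []
    for name, (frame, prev) in tables.items():
        merged = frame.merge(out, on="patient_id", how="inner")
        n_dropped = max(len(frame), len(out)) - len(merged)
        if len(merged) == 0:
            raise ValueError(f"{name}: no patients shared with the outcome table")
        if n_dropped:
            warnings.warn(
                f"{name}: {n_dropped} patient(s) without matching ids dropped",
                stacklevel=2,
            )
        roc = auc_rank(
            merged["code"].to_numpy(float),
            merged["hospital_death"].to_numpy(bool),
            Direction.positive,
            ci_method=ci_method,
        )
        rows.append(
            {
                "score": name,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "n_cases": roc.n_cases,
                "n_controls": roc.n_controls,
                "prevalence": prev,
            }
        )
    return pd.DataFrame(rows)


def render_screen_table(screen: pd.DataFrame, comparison: pd.DataFrame | None = None) -> str:
    """Plain-text rendering of the screen (and optional score comparison)."""
    lines = ["ROC analysis vs hospital mortality", ""]
    lines.append(f"{'Parameter':<18}{'AUC':>7}{'CI low':>9}{'CI high':>9}  Direction")
    for r in screen.itertuples(index=False):
        lines.append(
            f"{r.parameter:<18}{r.auc:>7.3f}{r.ci_low:>9.3f}{r.ci_high:>9.3f}  {r.direction}"
        )
    if comparison is not None:
        lines += ["", f"{'Score':<18}{'AUC':>7}{'CI low':>9}{'CI high':>9}{'Prevalence':>12}"]
        for r in comparison.itertuples(index=False):
            lines.append(
                f"{r.score:<18}{r.auc:>7.3f}{r.ci_low:>9.3f}{r.ci_high:>9.3f}"
                f"{r.prevalence:>11.1%}"
            )
    return "\n".join(lines)
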