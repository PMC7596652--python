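"""Fitted-model interface to the frailty score.

:class:`FifaModel` holds the cohort data (weekly profiles plus
outcomes); :meth:`FifaModel.fit` estimates the three category thresholds
by Youden-index maximisation and returns a :class:`FifaResults` carrying
the thresholds, the per-patient scores, the score's discrimination for
hospital mortality and a text summary. New cohorts are scored with
:meth:`FifaResults.predict`, which applies the fitted thresholds without
re-estimating them.
"""

from __future__ import annotations

import pandas as pd

from . import evaluation
from .aggregate import MIN_DAYS_DEFAULT, aggregate_weekly_frame
from .records import Direction, Parameter
from .roc import RocAnalysis, auc_rank
from .scoring import (
    DEFAULT_CATEGORY_MAP,
    Category,
    FifaConfig,
    assign_fifa_frame,
    derive_fifa_config,
    prevalence,
    _as_outcome_frame,
    _as_weekly_frame,
)

__all__ = ["FifaModel", "FifaResults"]


class FifaModel:
    """Frailty-score model for one monitored cohort.

    Parameters
    ----------
    weekly
        Weekly profile table (``patient_id``, ``n_days_used``, one column
        per tracker parameter) or a list of weekly profiles.
    outcomes
        Outcome table (``patient_id``, ``hospital_death``) or a list of
        outcome records.
    category_map
        Optional override of the category-to-parameter map; defaults to
        steps / maximum heart rate / overall stress.
    directions
        Optional per-category risk direction override.
    """

    def __init__(self, weekly, outcomes, category_map=None, directions=None):
        self.weekly = _as_weekly_frame(weekly)
        self.outcomes = _as_outcome_frame(outcomes)
        self.category_map = {
            Category(c): Parameter(p)
            for c, p in (category_map or DEFAULT_CATEGORY_MAP).items()
        }
        self.directions = {
            Category(c): Direction(d) for c, d in (directions or {}).items()
        }
        merged = self.weekly.merge(self.outcomes, on="patient_id", how="inner")
        if merged.empty:
            raise ValueError("weekly profiles and outcomes share no patient ids")
        self._merged = merged

    @classmethod
    def from_daily(
        cls,
        daily: pd.DataFrame,
        outcomes,
        *,
        min_days: int = MIN_DAYS_DEFAULT,
        category_map=None,
        directions=None,
    ) -> "FifaModel":
        """Build the model from the daily tracker table, applying the
        first/last-day trim and weekly averaging."""
        weekly, _ = aggregate_weekly_frame(daily, min_days=min_days)
        return cls(weekly, outcomes, category_map=category_map, directions=directions)

    def fit(self, *, ci_method: str = "hanley-mcneil") -> "FifaResults":
        """Estimate category thresholds and score the cohort."""
        config = derive_fifa_config(
            self.weekly,
            self.outcomes,
            category_map=self.category_map,
            directions=self.directions or None,
        )
        return FifaResults(self, config, ci_method=ci_method)


class FifaResults:
    """Fitted thresholds, per-patient scores and their discrimination."""

    def __init__(self, model: FifaModel, config: FifaConfig, *, ci_method="hanley-mcneil"):
        self.model = model
        self.config = config
        self.ci_method = ci_method
        self.thresholds = config.thresholds
        merged = model._merged
        self.scores = assign_fifa_frame(merged, config)
        self.prevalence = prevalence(self.scores)
        self.roc: RocAnalysis = auc_rank(
            self.scores["total"].to_numpy(float),
            merged["hospital_death"].to_numpy(bool),
            Direction.positive,
            ci_method=ci_method,
        )
        self.auc = self.roc.auc
        self.conf_int = (self.roc.ci_low, self.roc.ci_high)
        self.stage_counts = (
            self.scores["stage"].value_counts().reindex(
                ["no_frailty", "mild_frailty", "moderate_frailty", "severe_frailty"],
                fill_value=0,
            )
        )

    def predict(self, weekly) -> pd.DataFrame:
        """Score a (possibly new) weekly table with the fitted thresholds."""
        return assign_fifa_frame(_as_weekly_frame(weekly), self.config)

    def parameter_screen(self, directions=None) -> pd.DataFrame:
        """Single-parameter ROC screen on the fitting cohort."""
        return evaluation.parameter_screen(
            self.model.weekly, self.model.outcomes, directions, ci_method=self.ci_method
        )

    def compare(self, efs=None, gait=None) -> pd.DataFrame:
        """Head-to-head ROC comparison with the conventional instruments."""
        return evaluation.compare_scores(
            self.scores,
            efs=efs,
            gait=gait,
            outcomes=self.model.outcomes,
            ci_method=self.ci_method,
        )

    def plot_roc(self, ax=None, label: str | None = None):
        """Plot the score's empirical ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.roc.curve
        ax.plot(curve[:, 0], curve[:, 1], drawstyle="default",
                label=label or f"FIFA (AUC {self.auc:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Statsmodels-style text summary of the fitted score."""
        n = len(self.scores)
        lines = [
            "Fitness-tracker frailty score".center(62),
            "=" * 62,
            f"No. patients: {n:>5}    Deaths: {self.roc.n_cases}"
            f"    Frailty prevalence: {self.prevalence:.1%}",
            "-" * 62,
            f"{'Category':<12}{'Parameter':<17}{'Dir':<5}{'Cutoff':>9}"
            f"{'J':>6}{'Sens':>6}{'Spec':>6}",
        ]
        for cat, spec in self.thresholds.items():
            lines.append(
                f"{cat.value:<12}{spec.parameter.value:<17}"
                f"{'+' if spec.direction is Direction.positive else '-':<5}"
                f"{spec.cutoff:>9.2f}{spec.j_value:>6.2f}"
                f"{spec.sensitivity:>6.2f}{spec.specificity:>6.2f}"
            )
        lines += ["-" * 62, "Stage distribution:"]
        for stage, count in self.stage_counts.items():
            lines.append(f"  {stage:<18}{count:>4}")
        lines += [
            "-" * 62,
            f"Hospital-mortality AUC: {self.auc:.3f} "
            f"(95% CI {self.conf_int[0]:.3f}-{self.conf_int[1]:.3f}, "
            f"{self.ci_method})",
            "=" * 62,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<FifaResults n={len(self.scores)} auc={self.auc:.3f} "
            f"prevalence={self.prevalence:.3f}>"
        )
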