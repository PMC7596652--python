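"""ROC construction, rank-based AUC with confidence interval, and
Youden-index cutpoint derivation.

The AUC is computed through the Mann-Whitney identity — the probability
that a randomly chosen case outranks a randomly chosen control, tied
pairs counted one half (midranks) — which equals the trapezoidal area
under the empirical ROC curve. Confidence intervals use the Hanley-McNeil
large-sample standard error by default; the DeLong covariance estimator
is available as an alternative.

Cutpoints maximise the Youden index J = sensitivity + specificity - 1
over midpoints between consecutive distinct observed values (plus
infinite sentinels), so a cutoff never coincides with an observed value
on continuous inputs. Classification is strict: a positive-direction
category calls the event when value > cutoff, a negative-direction one
when value < cutoff; values equal to the cutoff are non-events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import Direction, Parameter

__all__ = [
    "RocAnalysis",
    "ThresholdSpec",
    "auc_rank",
    "youden_threshold",
    "roc_curve",
    "UndefinedAucError",
]


class UndefinedAucError(ValueError):
    """AUC is undefined without at least one case and one control."""


@dataclass
class RocAnalysis:
    """Discrimination of a scalar predictor for a binary outcome.

    ``curve`` is an array of (1 - specificity, sensitivity) points from
    (0, 0) to (1, 1), both coordinates non-decreasing. ``degenerate`` is
    set when the predictor is constant, in which case the AUC is exactly
    0.5 and the interval is uninformative.
    """

    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    direction: Direction
    curve: np.ndarray
    se: float
    ci_method: str = "hanley-mcneil"
    degenerate: bool = False

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.auc <= self.ci_high <= 1.0


@dataclass
class ThresholdSpec:
    """A Youden-optimal operating point for one scored parameter."""

    direction: Direction
    cutoff: float
    j_value: float
    sensitivity: float
    specificity: float
    parameter: Parameter | None = None

    def __post_init__(self) -> None:
        # J is stored as derived from the operating point, never separately.
        assert self.j_value == self.sensitivity + self.specificity - 1.0

    def calls_event(self, value: float) -> bool:
        """Apply the strict-inequality classification rule."""
        if self.direction is Direction.positive:
            return value > self.cutoff
        return value < self.cutoff


def _prepare(values, outcomes, direction):
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and outcomes must be equal-length 1-d sequences")
    if np.isnan(v).any():
        raise ValueError("predictor values must be non-null")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAucError(
            f"AUC undefined with {n1} cases and {n0} controls"
        )
    direction = Direction(direction)
    return direction.orient(v), y, n1, n0, direction


def _auc_midrank(v: np.ndarray, y: np.ndarray, n1: int, n0: int) -> float:
    ranks = stats.rankdata(v)  # midranks handle ties
    return (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(v: np.ndarray, y: np.ndarray) -> float:
    """DeLong structural-components standard error of the AUC."""
    x, w = v[y], v[~y]
    n1, n0 = len(x), len(w)
    psi = (x[:, None] > w[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == w[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(np.sqrt(s10 / n1 + s01 / n0))


def roc_curve(values, outcomes, direction=Direction.positive) -> np.ndarray:
    """Empirical ROC curve as (1 - specificity, sensitivity) points.

    One point per distinct predictor value plus the (0, 0) anchor; the
    trapezoidal area under the returned polyline equals the midrank AUC.
    """
    v, y, n1, n0, _ = _prepare(values, outcomes, direction)
    order = np.argsort(-v, kind="stable")
    v_sorted = v[order]
    y_sorted = y[order]
    # collapse ties: cumulative counts at the last index of each distinct value
    distinct = np.r_[np.nonzero(np.diff(v_sorted))[0], len(v_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return np.column_stack([fpr, tpr])


def auc_rank(
    values,
    outcomes,
    direction=Direction.positive,
    *,
    ci_method: str = "hanley-mcneil",
    alpha: float = 0.05,
) -> RocAnalysis:
    """Rank-based AUC of a scalar predictor for a binary outcome.

    Parameters
    ----------
    values, outcomes
        Equal-length sequences; ``outcomes`` is the binary event indicator.
    direction
        ``positive`` if larger values indicate the event; ``negative``
        computes the AUC on negated values.
    ci_method
        ``"hanley-mcneil"`` (default) or ``"delong"``.
    alpha
        Two-sided miscoverage for the normal-approximation interval.
    """
    v, y, n1, n0, direction = _prepare(values, outcomes, direction)
    degenerate = bool(np.all(v == v[0]))
    auc = _auc_midrank(v, y, n1, n0)
    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, n1, n0)
    elif ci_method == "delong":
        se = _delong_se(v, y)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    lo, hi = min(lo, auc), max(hi, auc)
    return RocAnalysis(
        auc=float(auc),
        ci_low=lo,
        ci_high=hi,
        n_cases=n1,
        n_controls=n0,
        direction=direction,
        curve=roc_curve(values, outcomes, direction),
        se=se,
        ci_method=ci_method,
        degenerate=degenerate,
    )


def youden_threshold(
    values, outcomes, direction=Direction.positive, parameter=None
) -> ThresholdSpec:
    """Youden-optimal cutoff for calling the event from a scalar predictor.

    Scans every candidate cutoff — the midpoints between consecutive
    distinct sorted values, plus -inf and +inf sentinels — and returns the
    one maximising J = sensitivity + specificity - 1. Ties on J are broken
    in favour of the higher sensitivity (a frailty screen should not miss
    cases), then the smaller cutoff.
    """
    v, y, n1, n0, direction = _prepare(values, outcomes, direction)
    distinct = np.unique(v)  # sorted ascending, on the oriented scale
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cands = np.r_[-np.inf, mids, np.inf]
    # oriented rule: event iff oriented value > cutoff. All comparisons in
    # integer counts so ties on J and sensitivity are exact.
    case_sorted = np.sort(v[y])
    ctrl_sorted = np.sort(v[~y])
    tp = n1 - np.searchsorted(case_sorted, cands, side="right")
    tn = np.searchsorted(ctrl_sorted, cands, side="right")
    j_num = tp * n0 + tn * n1  # J = j_num / (n1 * n0) - 1
    tied = np.flatnonzero(j_num == j_num.max())
    tied = tied[tp[tied] == tp[tied].max()]
    if direction is Direction.positive:
        idx = tied[np.argmin(cands[tied])]
        cutoff = cands[idx]
    else:
        # oriented cutoffs are on the negated scale: smallest original
        # cutoff = largest oriented one
        idx = tied[np.argmax(cands[tied])]
        cutoff = -cands[idx]
    s, p = tp[idx] / n1, tn[idx] / n0
    return ThresholdSpec(
        direction=direction,
        cutoff=float(cutoff),
        j_value=s + p - 1.0,
        sensitivity=s,
        specificity=p,
        parameter=Parameter(parameter) if parameter is not None else None,
    )
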