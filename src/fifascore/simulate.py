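"""Synthetic cohorts of daily wearable records with a latent-frailty
structure.

Each patient carries a single latent frailty factor ``f ~ N(0, 1)``. Every
tracker channel's patient-level mean is a channel baseline plus a loading
times ``f``; daily values add iid Gaussian noise and are clipped to the
channel's physical range. In-hospital death is Bernoulli with
``logit p = baseline_death_logit + frailty_effect * f``, so channels with
non-zero loading carry a mortality signal whose direction is the sign of
``loading * frailty_effect``.

Default loadings place the signal in the stress and heart-rate channels
(positive for overall stress, high-stress minutes and maximum heart rate;
negative for resting minutes), a weak protective signal in walking, and
none in sleep — the structure a preprocedural frailty screen in an
elderly TAVR cohort assumes. The true latent table (frailty, death
probability) is returned so tests can use the Bayes-optimal predictor as
an oracle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .records import DailyRecord, OutcomeRecord, Parameter

__all__ = ["CohortSimConfig", "SimulatedCohort", "simulate_cohort"]


#: Channel baselines: plausible values for an elderly pre-intervention
#: cohort (sedentary step counts, elevated resting stress). Units follow
#: the daily-record fields.
DEFAULT_BASELINES: dict[Parameter, float] = {
    Parameter.steps: 4000.0,
    Parameter.distance_km: 2.5,
    Parameter.hr_min: 55.0,
    Parameter.hr_max: 110.0,
    Parameter.stress_overall: 35.0,
    Parameter.stress_high_min: 60.0,
    Parameter.stress_rest_min: 600.0,
    Parameter.sleep_deep_min: 60.0,
    Parameter.sleep_light_min: 300.0,
    Parameter.sleep_awake_min: 45.0,
}

#: Loading of the latent frailty factor on each channel's patient mean.
#: Signs follow the observed direction of association with mortality;
#: magnitudes make the stress channels the strongest discriminators,
#: walking weak, sleep null.
DEFAULT_LOADINGS: dict[Parameter, float] = {
    Parameter.steps: -300.0,
    Parameter.distance_km: -0.2,
    Parameter.hr_min: 2.0,
    Parameter.hr_max: 7.0,
    Parameter.stress_overall: 9.0,
    Parameter.stress_high_min: 25.0,
    Parameter.stress_rest_min: -70.0,
    Parameter.sleep_deep_min: 0.0,
    Parameter.sleep_light_min: 0.0,
    Parameter.sleep_awake_min: 0.0,
}

#: Within-patient day-to-day standard deviation per channel.
DEFAULT_NOISE_SD: dict[Parameter, float] = {
    Parameter.steps: 1200.0,
    Parameter.distance_km: 0.8,
    Parameter.hr_min: 4.0,
    Parameter.hr_max: 7.0,
    Parameter.stress_overall: 7.0,
    Parameter.stress_high_min: 20.0,
    Parameter.stress_rest_min: 70.0,
    Parameter.sleep_deep_min: 15.0,
    Parameter.sleep_light_min: 45.0,
    Parameter.sleep_awake_min: 12.0,
}

# sleep_total_min is derived as deep + light + awake, never sampled.
_SAMPLED = [p for p in Parameter if p is not Parameter.sleep_total_min]


@dataclass
class CohortSimConfig:
    """Study conditions for one simulated cohort.

    ``frailty_effect`` is the logistic slope linking latent frailty to
    death; ``baseline_death_logit`` of -2.75 gives ~6% baseline
    mortality. ``channel_loadings`` and ``noise_sd`` may override any
    subset of channels; ``sleep_total_min`` entries are ignored because
    total sleep is derived from its components.
    """

    n_patients: int = 50
    days_per_patient: int = 9  # 7 retained after first/last-day trimming
    seed: int = 0
    frailty_effect: float = 2.0
    baseline_death_logit: float = -2.75
    channel_loadings: dict[Parameter, float] = field(default_factory=dict)
    noise_sd: dict[Parameter, float] = field(default_factory=dict)
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.days_per_patient < 3:
            raise ValueError("days_per_patient must be >= 3")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        self.channel_loadings = {
            Parameter(k): float(v) for k, v in self.channel_loadings.items()
        }
        self.noise_sd = {Parameter(k): float(v) for k, v in self.noise_sd.items()}
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")

    def resolved_loadings(self) -> dict[Parameter, float]:
        return {p: self.channel_loadings.get(p, DEFAULT_LOADINGS[p]) for p in _SAMPLED}

    def resolved_noise(self) -> dict[Parameter, float]:
        return {p: self.noise_sd.get(p, DEFAULT_NOISE_SD[p]) for p in _SAMPLED}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["channel_loadings"] = {p.value: v for p, v in self.resolved_loadings().items()}
        d["noise_sd"] = {p.value: v for p, v in self.resolved_noise().items()}
        d["baselines"] = {p.value: v for p, v in DEFAULT_BASELINES.items()}
        return json.dumps(d, indent=2)


@dataclass
class SimulatedCohort:
    """Daily records, outcomes and the generating latent truth."""

    daily: pd.DataFrame
    outcomes: pd.DataFrame
    latent: pd.DataFrame
    config: CohortSimConfig

    def daily_records(self) -> list[DailyRecord]:
        cols = [p.value for p in Parameter]
        return [
            DailyRecord(
                patient_id=str(r.patient_id),
                day_index=int(r.day_index),
                **{
                    c: (None if pd.isna(getattr(r, c)) else float(getattr(r, c)))
                    for c in cols
                },
            )
            for r in self.daily.itertuples(index=False)
        ]

    def outcome_records(self) -> list[OutcomeRecord]:
        return [
            OutcomeRecord(str(r.patient_id), bool(r.hospital_death))
            for r in self.outcomes.itertuples(index=False)
        ]


def simulate_cohort(config: CohortSimConfig | None = None, **kwargs) -> SimulatedCohort:
    """Draw one cohort under the single-factor latent-frailty model.

    Keyword arguments are forwarded to :class:`CohortSimConfig` when no
    config object is given. Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = CohortSimConfig(**kwargs)
    rng = np.random.default_rng(config.seed)
    n, d = config.n_patients, config.days_per_patient
    loadings = config.resolved_loadings()
    noise = config.resolved_noise()

    frailty = rng.standard_normal(n)
    raw: dict[Parameter, np.ndarray] = {}
    for p in _SAMPLED:
        mean = DEFAULT_BASELINES[p] + loadings[p] * frailty
        raw[p] = mean[:, None] + noise[p] * rng.standard_normal((n, d))

    # physical-range clipping (after noise; slightly attenuates extremes)
    for p in _SAMPLED:
        raw[p] = np.clip(raw[p], 0.0, None)
    raw[Parameter.stress_overall] = np.clip(raw[Parameter.stress_overall], 0.0, 100.0)
    # heart-rate pair: joint construction keeps hr_min <= hr_max per day
    lo = np.minimum(raw[Parameter.hr_min], raw[Parameter.hr_max])
    hi = np.maximum(raw[Parameter.hr_min], raw[Parameter.hr_max])
    raw[Parameter.hr_min], raw[Parameter.hr_max] = lo, hi
    # stress minutes cannot exceed the day
    tot = raw[Parameter.stress_high_min] + raw[Parameter.stress_rest_min]
    over = tot > 1440.0
    if over.any():
        scale = np.where(over, 1440.0 / np.where(over, tot, 1.0), 1.0)
        raw[Parameter.stress_high_min] *= scale
        raw[Parameter.stress_rest_min] *= scale
    raw[Parameter.steps] = np.round(raw[Parameter.steps])
    sleep_total = (
        raw[Parameter.sleep_deep_min]
        + raw[Parameter.sleep_light_min]
        + raw[Parameter.sleep_awake_min]
    )

    width = len(str(n))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)])
    daily = pd.DataFrame(
        {
            "patient_id": np.repeat(ids, d),
            "day_index": np.tile(np.arange(d), n),
        }
    )
    columns = dict(raw)
    columns[Parameter.sleep_total_min] = sleep_total
    for p in Parameter:
        vals = columns[p].ravel().astype(float)
        if config.missing_rate > 0.0:
            mask = rng.random(vals.shape) < config.missing_rate
            vals = np.where(mask, np.nan, vals)
        daily[p.value] = vals

    death_prob = expit(config.baseline_death_logit + config.frailty_effect * frailty)
    death = rng.random(n) < death_prob
    outcomes = pd.DataFrame({"patient_id": ids, "hospital_death": death})
    latent = pd.DataFrame(
        {
            "patient_id": ids,
            "frailty": frailty,
            "death_prob": death_prob,
            "hospital_death": death,
        }
    )
    return SimulatedCohort(daily=daily, outcomes=outcomes, latent=latent, config=config)
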