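"""Reusable simulation studies of the frailty score's operating
characteristics.

Two studies are provided. The null-calibration study checks that the
score carries no artefactual signal when the generator links nothing to
mortality: thresholds are fitted on one null cohort and evaluated on an
independent one, because thresholds chosen retrospectively by Youden
maximisation are optimistically biased on their own fitting data. The
planted-effect study plants the mortality signal in a single stress
channel and asks whether the derived cutoff lands between the survivor
and non-survivor means (the discriminating region) and whether the
composite score out-discriminates the channels that carry little or no
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregate import aggregate_weekly_frame
from .model import FifaModel
from .records import Direction, Parameter
from .roc import UndefinedAucError, auc_rank
from .scoring import Category
from .simulate import CohortSimConfig, simulate_cohort

__all__ = [
    "NullCalibrationResult",
    "PlantedEffectResult",
    "null_calibration_study",
    "planted_effect_study",
]

_SEED_CAP = 2**31 - 1


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, _SEED_CAP, size=n)


@dataclass
class NullCalibrationResult:
    aucs: np.ndarray          # held-out FIFA AUC per usable replicate
    n_replicates: int         # replicates attempted
    n_valid: int              # replicates with >= 1 death in both cohorts

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def se_mean(self) -> float:
        return float(self.aucs.std(ddof=1) / np.sqrt(len(self.aucs)))


def null_calibration_study(
    n_replicates: int = 200, n_patients: int = 50, seed: int = 0
) -> NullCalibrationResult:
    """Held-out FIFA AUC under a null generator (no frailty effect).

    Each replicate fits thresholds on one null cohort and measures the
    score's AUC on a second, independently drawn null cohort. Replicates
    where either cohort has no deaths (or no survivors) are skipped —
    the AUC is undefined there.
    """
    seeds = _rep_seeds(seed, 2 * n_replicates).reshape(n_replicates, 2)
    aucs = []
    for train_seed, test_seed in seeds:
        train = simulate_cohort(
            n_patients=n_patients, seed=int(train_seed), frailty_effect=0.0
        )
        test = simulate_cohort(
            n_patients=n_patients, seed=int(test_seed), frailty_effect=0.0
        )
        try:
            results = FifaModel.from_daily(train.daily, train.outcomes).fit()
            weekly, _ = aggregate_weekly_frame(test.daily)
            scores = results.predict(weekly).merge(test.outcomes, on="patient_id")
            roc = auc_rank(
                scores["total"].to_numpy(float),
                scores["hospital_death"].to_numpy(bool),
                Direction.positive,
            )
        except UndefinedAucError:
            continue
        aucs.append(roc.auc)
    return NullCalibrationResult(
        aucs=np.asarray(aucs), n_replicates=n_replicates, n_valid=len(aucs)
    )


#: Planted scenario: the whole mortality signal sits in the overall
#: stress level; walking gets a token (misloaded) effect and every other
#: channel none.
PLANTED_LOADINGS: dict[Parameter, float] = {
    **{p: 0.0 for p in Parameter if p is not Parameter.sleep_total_min},
    Parameter.stress_overall: 9.0,
    Parameter.steps: -50.0,
}

#: Channels scored or screened despite carrying little to no signal.
MISLOADED_CHANNELS = (Parameter.steps, Parameter.hr_max, Parameter.sleep_light_min)


@dataclass
class PlantedEffectResult:
    cutoff_in_region: np.ndarray   # bool per replicate
    fifa_beats_all: np.ndarray     # bool per replicate
    fifa_aucs: np.ndarray
    stress_cutoffs: np.ndarray
    n_replicates: int

    @property
    def cutoff_recovery_rate(self) -> float:
        return float(self.cutoff_in_region.mean())

    @property
    def fifa_beats_rate(self) -> float:
        return float(self.fifa_beats_all.mean())


def planted_effect_study(
    n_replicates: int = 200, n_patients: int = 2000, seed: int = 0
) -> PlantedEffectResult:
    """Recovery of a planted single-channel (stress) mortality effect.

    Per replicate: the derived stress cutoff should fall inside the
    planted discriminating region — between the survivors' and the
    non-survivors' mean weekly stress — and the composite score's AUC
    should exceed that of every channel carrying no planted signal.
    """
    seeds = _rep_seeds(seed, n_replicates)
    in_region, beats, fifa_aucs, cutoffs = [], [], [], []
    for rep_seed in seeds:
        cohort = simulate_cohort(
            CohortSimConfig(
                n_patients=n_patients,
                seed=int(rep_seed),
                channel_loadings=dict(PLANTED_LOADINGS),
            )
        )
        results = FifaModel.from_daily(cohort.daily, cohort.outcomes).fit()
        cutoff = results.thresholds[Category.stress].cutoff
        merged = results.model._merged
        died = merged["hospital_death"].to_numpy(bool)
        stress = merged[Parameter.stress_overall.value].to_numpy(float)
        lo, hi = stress[~died].mean(), stress[died].mean()
        in_region.append(bool(min(lo, hi) < cutoff < max(lo, hi)))
        cutoffs.append(cutoff)
        fifa_aucs.append(results.auc)
        channel_aucs = [
            auc_rank(
                merged[p.value].to_numpy(float), died, Direction.positive
                if p is not Parameter.steps else Direction.negative,
            ).auc
            for p in MISLOADED_CHANNELS
        ]
        beats.append(bool(results.auc > max(channel_aucs)))
    return PlantedEffectResult(
        cutoff_in_region=np.asarray(in_region),
        fifa_beats_all=np.asarray(beats),
        fifa_aucs=np.asarray(fifa_aucs),
        stress_cutoffs=np.asarray(cutoffs),
        n_replicates=n_replicates,
    )
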