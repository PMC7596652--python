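import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fifascore as fs
from fifascore.records import Direction, Parameter
from fifascore.roc import ThresholdSpec
from fifascore.scoring import Category, FifaConfig, ScoringError, Stage
from conftest import make_profile


def _spec(param, direction, cutoff):
    return ThresholdSpec(
        direction=Direction(direction),
        cutoff=cutoff,
        j_value=0.0,
        sensitivity=0.5,
        specificity=0.5,
        parameter=Parameter(param),
    )


@pytest.fixture
def config():
    return FifaConfig(
        thresholds={
            Category.walking: _spec("steps", "negative", 3000.0),
            Category.heart_rate: _spec("hr_max", "positive", 115.0),
            Category.stress: _spec("stress_overall", "positive", 40.0),
        }
    )


def test_all_categories_breached_is_severe(config):
    p = make_profile(steps=1000, hr_max=130, stress_overall=60)
    r = fs.assign_fifa(p, config)
    assert r.total == 3 and r.stage is Stage.severe_frailty and r.frail_binary


def test_no_category_breached_is_no_frailty(config):
    p = make_profile(steps=8000, hr_max=100, stress_overall=20)
    r = fs.assign_fifa(p, config)
    assert r.total == 0 and r.stage is Stage.no_frailty and not r.frail_binary


def test_value_exactly_at_cutoff_scores_zero(config):
    # strict inequalities in both directions: one-line rule oracle
    rule = lambda v, c, pos: (v > c) if pos else (v < c)
    p = make_profile(steps=3000.0, hr_max=115.0, stress_overall=40.0)
    r = fs.assign_fifa(p, config)
    assert r.total == 0
    assert r.points[Category.stress] == int(rule(40.0, 40.0, True))


@pytest.mark.parametrize(
    ("total", "stage", "frail"),
    [(0, Stage.no_frailty, False), (1, Stage.mild_frailty, False),
     (2, Stage.moderate_frailty, True), (3, Stage.severe_frailty, True)],
)
def test_stage_map_and_binary_definition(total, stage, frail):
    assert Stage(total) is stage
    assert (stage in (Stage.moderate_frailty, Stage.severe_frailty)) is frail


def test_borderline_is_an_alias_for_mild():
    assert Stage.parse("borderline") is Stage.mild_frailty
    assert Stage.parse("moderate") is Stage.moderate_frailty
    assert Stage.parse(2) is Stage.moderate_frailty


def test_missing_configured_value_names_patient_and_parameter(config):
    p = make_profile(patient_id="P77", steps=1000, hr_max=None, stress_overall=60)
    with pytest.raises(ScoringError, match=r"P77.*hr_max"):
        fs.assign_fifa(p, config)


def test_config_requires_three_distinct_parameters():
    with pytest.raises(ValueError, match="three categories"):
        FifaConfig(thresholds={Category.walking: _spec("steps", "negative", 1.0)})
    with pytest.raises(ValueError, match="distinct"):
        FifaConfig(
            thresholds={
                Category.walking: _spec("steps", "negative", 1.0),
                Category.heart_rate: _spec("steps", "negative", 2.0),
                Category.stress: _spec("stress_overall", "positive", 3.0),
            }
        )


@given(
    st.floats(500, 8000, allow_nan=False),
    st.floats(80, 150, allow_nan=False),
    st.floats(0, 100, allow_nan=False),
    st.sampled_from(list(Category)),
    st.floats(1, 500),
)
def test_worsening_one_category_never_lowers_the_score(
    steps, hr_max, stress, category, delta
):
    cfg = FifaConfig(
        thresholds={
            Category.walking: _spec("steps", "negative", 3000.0),
            Category.heart_rate: _spec("hr_max", "positive", 115.0),
            Category.stress: _spec("stress_overall", "positive", 40.0),
        }
    )
    base = {"steps": steps, "hr_max": hr_max, "stress_overall": min(stress, 100.0)}
    worse = dict(base)
    key = cfg.thresholds[category].parameter.value
    if cfg.thresholds[category].direction is Direction.positive:
        worse[key] = min(worse[key] + delta, 100.0 if key == "stress_overall" else 1e9)
    else:
        worse[key] = max(worse[key] - delta, 0.0)
    r0 = fs.assign_fifa(make_profile(**base), cfg)
    r1 = fs.assign_fifa(make_profile(**worse), cfg)
    assert r1.total >= r0.total
    assert r1.stage >= r0.stage


def test_frame_and_record_scoring_agree(config, weekly_outcomes):
    weekly, _ = weekly_outcomes
    frame = fs.assign_fifa_frame(weekly, config)
    from fifascore.aggregate import profiles_from_frame

    for profile, row in zip(profiles_from_frame(weekly), frame.itertuples(index=False)):
        r = fs.assign_fifa(profile, config)
        assert r.total == row.total and r.stage.name == row.stage


def test_scoring_is_invariant_to_patient_order(config, weekly_outcomes):
    weekly, _ = weekly_outcomes
    shuffled = weekly.sample(frac=1.0, random_state=4)
    a = fs.assign_fifa_frame(weekly, config).set_index("patient_id")
    b = fs.assign_fifa_frame(shuffled, config).set_index("patient_id").loc[a.index]
    pd.testing.assert_frame_equal(a, b)


def test_stage_partition_counts_sum_to_cohort(config, weekly_outcomes):
    weekly, _ = weekly_outcomes
    frame = fs.assign_fifa_frame(weekly, config)
    assert frame["stage"].value_counts().sum() == len(weekly)


def test_prevalence_counting(rng):
    frame = pd.DataFrame({"frail_binary": [True, False, True, True]})
    assert fs.prevalence(frame) == 0.75
    results = [
        fs.FifaResult("P", {}, t, Stage(t), Stage(t) >= Stage.moderate_frailty)
        for t in rng.integers(0, 4, size=40)
    ]
    direct = sum(r.total >= 2 for r in results) / 40
    assert fs.prevalence(results) == direct
    assert fs.prevalence([r for r in results if r.total == 3]) == 1.0
    assert fs.prevalence([r for r in results if r.total <= 1] or
                         [fs.FifaResult("x", {}, 0, Stage(0), False)]) == 0.0
    with pytest.raises(ValueError, match="empty"):
        fs.prevalence([])


def test_derive_on_perfectly_separated_cohort_gives_j1():
    rows = []
    deaths = []
    for i in range(10):
        dead = i < 3
        rows.append(
            {
                "patient_id": f"P{i}",
                "n_days_used": 7,
                "steps": 1000.0 if dead else 6000.0,
                "hr_max": 130.0 if dead else 100.0,
                "stress_overall": 70.0 if dead else 30.0,
            }
        )
        deaths.append({"patient_id": f"P{i}", "hospital_death": dead})
    weekly = pd.DataFrame(rows)
    for p in Parameter:
        if p.value not in weekly:
            weekly[p.value] = 50.0
    outcomes = pd.DataFrame(deaths)
    cfg = fs.derive_fifa_config(weekly, outcomes)
    assert all(t.j_value == 1.0 for t in cfg.thresholds.values())
    res = fs.FifaModel(weekly, outcomes).fit()
    assert res.auc == 1.0
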