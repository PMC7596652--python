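import numpy as np
import pytest
from hypothesis import given, strategies as st

from fifascore import Direction, auc_rank, roc_curve, youden_threshold
from fifascore.roc import UndefinedAucError


def brute_force_auc(values, outcomes):
    """Exhaustive case-control pair enumeration, ties counted one half."""
    v = np.asarray(values, float)
    y = np.asarray(outcomes, bool)
    cases, controls = v[y], v[~y]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def exhaustive_youden(values, outcomes, direction=Direction.positive):
    """Evaluate J at every candidate cutoff by direct counting.

    Comparisons use the integer numerator TP*n0 + TN*n1 so ties on J and
    on sensitivity are exact.
    """
    v = np.asarray(values, float)
    y = np.asarray(outcomes, bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    s = np.unique(v)
    mids = [(a + b) / 2 for a, b in zip(s[:-1], s[1:])]
    cands = [-np.inf, *mids, np.inf]
    best = None
    for c in cands:
        if direction is Direction.positive:
            called = v > c
        else:
            called = v < c
        tp = int((called & y).sum())
        tn = int((~called & ~y).sum())
        key = (tp * n0 + tn * n1, tp, -c)  # max J, max sens, min cutoff
        if best is None or key > best[0]:
            best = (key, c, tp / n1 + tn / n0 - 1)
    return best[1], best[2]


def test_published_count_structure_gives_0844(published_counts):
    totals, deaths = published_counts
    r = auc_rank(totals, deaths)
    assert r.auc == pytest.approx(119 / 141, abs=1e-15)
    assert round(r.auc, 3) == 0.844
    assert (r.n_cases, r.n_controls) == (3, 47)


def test_perfect_separation():
    r = auc_rank([1, 2, 3], [0, 0, 1])
    assert r.auc == 1.0
    assert any(np.allclose(pt, [0, 1]) for pt in r.curve)


def test_tied_values_counted_one_half():
    # controls [5,7,7], cases [7,9] -> 5/6 by pairwise enumeration
    values = [5, 7, 7, 7, 9]
    outcomes = [0, 0, 0, 1, 1]
    r = auc_rank(values, outcomes)
    assert r.auc == pytest.approx(5 / 6, abs=1e-15)
    assert r.auc == pytest.approx(brute_force_auc(values, outcomes), abs=1e-15)


def test_matches_sklearn_on_random_data(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(25):
        n = int(rng.integers(8, 60))
        v = rng.integers(0, 8, size=n).astype(float)
        y = rng.random(n) < 0.3
        if y.all() or not y.any():
            continue
        assert auc_rank(v, y).auc == pytest.approx(roc_auc_score(y, v), abs=1e-12)


def test_negative_direction_complements_positive(rng):
    for _ in range(20):
        n = int(rng.integers(6, 40))
        v = rng.integers(0, 5, size=n).astype(float)
        y = np.r_[True, False, rng.random(n - 2) < 0.4]
        pos = auc_rank(v, y, Direction.positive).auc
        neg = auc_rank(v, y, Direction.negative).auc
        assert pos + neg == pytest.approx(1.0, abs=1e-12)


@given(st.integers(0, 2**32 - 1).map(np.random.default_rng))
def test_auc_invariant_under_monotone_transform(g):
    n = 30
    v = g.uniform(0, 10, n)
    y = np.r_[True, False, g.random(n - 2) < 0.3]
    base = auc_rank(v, y).auc
    assert auc_rank(np.exp(v), y).auc == pytest.approx(base, abs=1e-12)
    assert auc_rank(3 * v - 7, y).auc == pytest.approx(base, abs=1e-12)


def test_trapezoid_over_curve_equals_rank_auc(rng):
    for _ in range(20):
        n = int(rng.integers(6, 50))
        v = rng.integers(0, 6, size=n).astype(float)
        y = np.r_[True, False, rng.random(n - 2) < 0.35]
        r = auc_rank(v, y)
        area = np.trapezoid(r.curve[:, 1], r.curve[:, 0])
        assert area == pytest.approx(r.auc, abs=1e-12)
        assert np.all(np.diff(r.curve[:, 0]) >= 0)
        assert np.all(np.diff(r.curve[:, 1]) >= 0)
        assert np.allclose(r.curve[0], [0, 0]) and np.allclose(r.curve[-1], [1, 1])


def test_constant_predictor_is_degenerate():
    r = auc_rank([5, 5, 5, 5], [0, 1, 0, 1])
    assert r.auc == 0.5 and r.degenerate
    t = youden_threshold([5, 5, 5, 5], [0, 1, 0, 1])
    assert t.j_value == 0.0


def test_undefined_without_cases_or_controls():
    with pytest.raises(UndefinedAucError):
        auc_rank([1, 2], [0, 0])
    with pytest.raises(UndefinedAucError):
        youden_threshold([1, 2], [1, 1])


def test_ci_ordering_and_clipping(rng):
    for method in ("hanley-mcneil", "delong"):
        r = auc_rank([1, 2, 3, 4], [0, 0, 1, 1], ci_method=method)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0
    with pytest.raises(ValueError, match="ci_method"):
        auc_rank([1, 2], [0, 1], ci_method="bootstrap")


def test_youden_perfect_separation_midpoint():
    t = youden_threshold([1, 2, 3, 4, 5], [0, 0, 0, 1, 1])
    assert (t.cutoff, t.j_value) == (3.5, 1.0)
    assert t.sensitivity == t.specificity == 1.0


def test_youden_tie_break_prefers_sensitivity():
    # cutoffs 1.5 and 3.5 both give J = 0.5; 1.5 has sensitivity 1
    t = youden_threshold([1, 2, 3, 4], [0, 1, 0, 1])
    assert t.cutoff == 1.5
    assert t.sensitivity == 1.0


def test_youden_negative_direction_semantics():
    t = youden_threshold([1, 2, 3, 4], [1, 1, 0, 0], Direction.negative)
    assert t.cutoff == 2.5 and t.j_value == 1.0
    assert t.calls_event(2.0) and not t.calls_event(2.5) and not t.calls_event(3.0)


def test_youden_matches_exhaustive_scan(rng):
    for _ in range(60):
        n = int(rng.integers(6, 31))
        v = rng.integers(0, 10, size=n).astype(float)
        y = np.r_[True, False, rng.random(n - 2) < 0.4]
        for direction in Direction:
            t = youden_threshold(v, y, direction)
            c_ref, j_ref = exhaustive_youden(v, y, direction)
            assert t.cutoff == c_ref
            assert t.j_value == pytest.approx(j_ref, abs=1e-12)


def test_youden_j_equals_max_over_roc_curve(rng):
    # J* = max over the ROC polyline of (sensitivity - (1 - specificity))
    for _ in range(20):
        n = int(rng.integers(8, 40))
        v = rng.integers(0, 6, size=n).astype(float)
        y = np.r_[True, False, rng.random(n - 2) < 0.4]
        t = youden_threshold(v, y)
        curve = roc_curve(v, y)
        assert t.j_value == pytest.approx((curve[:, 1] - curve[:, 0]).max(), abs=1e-12)
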