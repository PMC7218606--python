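import numpy as np
import pandas as pd
import pytest

import stepmetrics as sm
from stepmetrics import analysis as an
from stepmetrics.io_epoch import ConfigError

from oracles import naive_stepwise


def _frame(**cols):
    return pd.DataFrame(cols)


def test_outcome_identical_to_predictor_has_unit_r2():
    x = np.arange(10.0)
    res = sm.variance_explained(_frame(y=x, x=x), "y", "x")
    assert res.r_squared == pytest.approx(1.0)
    assert res.coefficients["x"] == pytest.approx(1.0)


def test_independent_predictor_explains_nothing():
    rng = np.random.default_rng(0)
    table = _frame(y=rng.normal(size=10_000), x=rng.normal(size=10_000))
    res = sm.variance_explained(table, "y", "x")
    assert res.r_squared < 0.01


def test_zero_variance_predictor_is_degenerate():
    table = _frame(y=np.arange(5.0), x=np.ones(5))
    with pytest.raises(an.DegeneratePredictorError):
        sm.variance_explained(table, "y", "x")


def test_small_sample_rejected():
    table = _frame(y=[1.0, 2.0], x=[1.0, 3.0])
    with pytest.raises(ConfigError):
        sm.variance_explained(table, "y", "x")


# ---------------------------------------------------------------------------
# Stepwise selection


def test_single_significant_predictor_is_selected():
    rng = np.random.default_rng(1)
    x = rng.normal(size=50)
    y = 2 * x + rng.normal(scale=0.5, size=50)
    table = _frame(y=y, x=x)
    res = sm.stepwise_select(table, "y", pool=["x"])
    assert res.selected == ["x"]
    assert res.r_squared == pytest.approx(
        sm.variance_explained(table, "y", "x").r_squared)


def test_duplicate_of_outcome_beats_noise_predictors():
    rng = np.random.default_rng(2)
    y = rng.normal(size=105)
    table = _frame(y=y, dup=y.copy(),
                   n1=rng.normal(size=105), n2=rng.normal(size=105),
                   n3=rng.normal(size=105))
    res = sm.stepwise_select(table, "y", pool=["n1", "dup", "n2", "n3"])
    assert res.selected[0] == "dup"
    assert res.selected == ["dup"]  # no noise variable passes afterwards


def test_tzc_is_refused_as_predictor():
    table = _frame(y=np.arange(10.0), tzc_min=np.arange(10.0))
    with pytest.raises(ConfigError):
        sm.stepwise_select(table, "y", pool=["tzc_min"])


def test_collinear_predictor_is_dropped_by_vif_rule():
    rng = np.random.default_rng(3)
    x1 = rng.normal(size=200)
    x2 = x1 + rng.normal(scale=0.05, size=200)       # VIF >> 7 with x1
    x3 = rng.normal(size=200)
    y = x1 + 0.5 * x3 + rng.normal(scale=0.3, size=200)
    res = sm.stepwise_select(_frame(y=y, x1=x1, x2=x2, x3=x3), "y",
                             pool=["x1", "x2", "x3"])
    assert "x2" not in res.selected or "x1" not in res.selected
    assert all(v <= 7 for v in res.vif.values())


def test_r2_is_nondecreasing_along_additions():
    table = sm.linear_cohort(n=105, seed=4)
    res = sm.stepwise_select(table, "mvpa_min")
    adds = [e["r_squared"] for e in res.increments if e["action"] == "add"]
    assert all(b >= a - 1e-12 for a, b in zip(adds, adds[1:]))


def test_selection_order_invariant_to_pool_permutation():
    table = sm.linear_cohort(n=105, seed=5)
    pool = list(an.STEP_PREDICTORS)
    res1 = sm.stepwise_select(table, "mvpa_min", pool=pool)
    res2 = sm.stepwise_select(table, "mvpa_min", pool=pool[::-1])
    assert set(res1.selected) == set(res2.selected)
    assert res1.r_squared == pytest.approx(res2.r_squared)


def test_stepwise_matches_brute_force_enumeration():
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        n = 40
        x = rng.normal(size=(n, 4))
        y = x @ np.array([1.0, 0.6, 0.0, 0.2]) + rng.normal(scale=0.8, size=n)
        table = pd.DataFrame(x, columns=["p1", "p2", "p3", "p4"])
        table["y"] = y
        want = naive_stepwise(table, "y", ["p1", "p2", "p3", "p4"])
        got = sm.stepwise_select(table, "y", pool=["p1", "p2", "p3", "p4"])
        assert got.selected == want


# ---------------------------------------------------------------------------
# Group comparison


def test_identical_groups_give_t0_p1():
    vals = np.tile(np.arange(10.0), 2)
    table = _frame(m=vals, meets_guideline=[True] * 10 + [False] * 10)
    res = sm.compare_groups(table, "m")
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_separated_groups_are_significant():
    rng = np.random.default_rng(6)
    table = _frame(m=np.r_[rng.normal(10, 1, 20), rng.normal(20, 1, 20)],
                   meets_guideline=[True] * 20 + [False] * 20)
    res = sm.compare_groups(table, "m")
    assert res.p < 1e-3
    assert res.n_meets == res.n_not == 20


def test_tiny_group_is_an_error():
    table = _frame(m=np.arange(10.0),
                   meets_guideline=[True] + [False] * 9)
    with pytest.raises(an.InsufficientGroupError):
        sm.compare_groups(table, "m")


def test_welch_variant_differs_under_unequal_variance():
    rng = np.random.default_rng(7)
    table = _frame(m=np.r_[rng.normal(0, 5, 10), rng.normal(1, 0.5, 60)],
                   meets_guideline=[True] * 10 + [False] * 60)
    pooled = sm.compare_groups(table, "m")
    welch = sm.compare_groups(table, "m", welch=True)
    assert pooled.p != pytest.approx(welch.p)


# ---------------------------------------------------------------------------
# Threshold inversion


def test_threshold_closed_form_on_noiseless_line():
    steps = np.linspace(2000, 15000, 50)
    table = _frame(mvpa_min=0.006 * steps, steps_per_day=steps)
    res = sm.guideline_threshold(table, "steps_per_day")
    assert res.threshold == pytest.approx(10_000.0)
    assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-6)


def test_nonpositive_or_insignificant_slope_is_not_invertible():
    steps = np.linspace(2000, 15000, 50)
    table = _frame(mvpa_min=100 - 0.006 * steps, steps_per_day=steps)
    with pytest.raises(an.NonInvertibleError):
        sm.guideline_threshold(table, "steps_per_day")
    rng = np.random.default_rng(8)
    table = _frame(mvpa_min=rng.normal(size=50), steps_per_day=steps)
    with pytest.raises(an.NonInvertibleError):
        sm.guideline_threshold(table, "steps_per_day")
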