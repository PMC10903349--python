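import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrrkit.behaviour import (
    chi_squared_homogeneity,
    daily_wing_means,
    first_record_table,
    mann_whitney_u,
    protandry_index,
    slope_difference_test,
    wing_decay_regression,
)
from mrrkit.events import CaptureEvent

from conftest import day


def _ev(iid, k, sex, behaviour="flying", **kw):
    return CaptureEvent(iid, day(k), sex, behaviour=behaviour, **kw)


def test_first_record_dedup_counts_each_individual_once():
    evs = [
        _ev("a", 0, "male", "flying"),
        _ev("a", 1, "male", "resting"),
        _ev("a", 2, "male", "basking"),
        _ev("b", 0, "female", "nectaring", nectar_genus="Knautia"),
    ]
    tab = first_record_table(evs, "sex", "behaviour", dedup=True)
    assert tab.loc["male"].sum() == 1
    assert tab.loc["male", "flying"] == 1  # earliest record wins
    no_dedup = first_record_table(evs, "sex", "behaviour", dedup=False)
    assert no_dedup.loc["male"].sum() == 3


def test_first_record_never_double_counts(sim_events):
    events, _ = sim_events
    tab = first_record_table(events, "sex", "behaviour", dedup=True)
    n_individuals = len({e.individual_id for e in events if e.behaviour})
    assert tab.to_numpy().sum() == n_individuals


def test_unknown_category_listed():
    evs = [_ev("a", 0, "male", "hovering")]
    with pytest.raises(ValueError, match="hovering"):
        first_record_table(evs, categories=("flying", "resting"))


def test_chi2_hand_computation():
    out = chi_squared_homogeneity(np.array([[10, 20], [20, 10]]))
    assert out["chi2"] == pytest.approx(6.667, abs=1e-3)
    assert out["df"] == 1
    assert out["p"] == pytest.approx(0.0098, abs=2e-4)


def test_chi2_homogeneous_rows():
    out = chi_squared_homogeneity(np.array([[10, 20, 30], [10, 20, 30]]))
    assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert out["p"] == pytest.approx(1.0)


def test_chi2_guards():
    with pytest.raises(ValueError):
        chi_squared_homogeneity(np.array([[1, 2]]))
    with pytest.raises(ValueError):
        chi_squared_homogeneity(np.array([[0, 5], [0, 7]]))


@given(
    st.lists(
        st.lists(st.integers(min_value=1, max_value=60), min_size=3, max_size=3),
        min_size=2, max_size=4,
    )
)
@settings(max_examples=50, deadline=None)
def test_chi2_equals_textbook_formula(rows):
    arr = np.asarray(rows, dtype=float)
    out = chi_squared_homogeneity(arr)
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    stat = ((arr - expected) ** 2 / expected).sum()
    assert out["chi2"] == pytest.approx(stat, rel=1e-10)


def test_daily_wing_means_arithmetic_and_threshold():
    evs = [_ev(f"i{j}", 0, "male", wing_score=s) for j, s in enumerate([1, 1, 2, 2, 4])]
    evs += [_ev(f"j{j}", 1, "male", wing_score=2) for j in range(4)]
    series = daily_wing_means(evs, "male")
    d0 = series[series["day"] == 0].iloc[0]
    assert d0["mean_score"] == pytest.approx(2.0)
    assert bool(d0["included"])
    assert not bool(series[series["day"] == 1]["included"].iloc[0])


def test_wing_wear_simulation_monotone(sim_events):
    """A wear process increasing with age yields increasing daily means."""
    events, _ = sim_events
    series = daily_wing_means(events, "male")
    use = series[series["included"]]
    reg = wing_decay_regression(series)
    assert reg["slope"] > 0
    # early-season mean below late-season mean
    assert use["mean_score"].iloc[:3].mean() < use["mean_score"].iloc[-3:].mean()


def test_wing_regression_flat_and_exact():
    flat = pd.DataFrame({"day": range(5), "mean_score": [2.0] * 5,
                         "n": [6] * 5, "included": [True] * 5})
    out = wing_decay_regression(flat)
    assert out["slope"] == pytest.approx(0.0, abs=1e-12)
    assert out["r2"] == pytest.approx(0.0, abs=1e-12)
    line = flat.assign(mean_score=1 + 0.09 * np.arange(5))
    out = wing_decay_regression(line)
    assert out["slope"] == pytest.approx(0.09)
    assert out["r2"] == pytest.approx(1.0)
    assert out["pearson_r"] == pytest.approx(1.0)


def test_excluded_days_carry_no_weight():
    s = pd.DataFrame({"day": range(6), "mean_score": [1, 1.2, 1.4, 1.6, 1.8, 9.0],
                      "n": [5, 5, 5, 5, 5, 2], "included": [True] * 5 + [False]})
    out = wing_decay_regression(s)
    assert out["slope"] == pytest.approx(0.2)


def test_slope_difference_identical_series():
    rng = np.random.default_rng(0)
    s = pd.DataFrame({"day": range(8),
                      "mean_score": 1 + 0.1 * np.arange(8) + rng.normal(0, 0.05, 8),
                      "n": [6] * 8, "included": [True] * 8})
    out = slope_difference_test(s, s.copy())
    assert out["p"] == pytest.approx(1.0, abs=1e-6)
    assert out["slope_a"] == pytest.approx(out["slope_b"])


def test_slope_difference_detects_contrast():
    rng = np.random.default_rng(1)
    days = np.arange(12)
    a = pd.DataFrame({"day": days, "mean_score": 1 + 0.09 * days + rng.normal(0, 0.03, 12),
                      "n": [6] * 12, "included": [True] * 12})
    b = pd.DataFrame({"day": days, "mean_score": 1 + 0.004 * days + rng.normal(0, 0.03, 12),
                      "n": [6] * 12, "included": [True] * 12})
    out = slope_difference_test(a, b)
    assert out["p"] < 0.05
    assert out["slope_a"] > out["slope_b"]


def test_mann_whitney_identical_samples():
    out = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert out["p"] == pytest.approx(1.0)


def test_mann_whitney_exact_separated_samples():
    out = mann_whitney_u([1, 2, 3], [10, 11, 12])
    assert out["U"] == 0.0
    assert out["method"] == "exact"
    assert out["p"] == pytest.approx(0.1)


def test_mann_whitney_matches_enumeration():
    """Exact p equals the proportion of label permutations with as-extreme U."""
    a = [1.0, 4.0, 6.0, 9.0]
    b = [2.0, 3.0, 8.0]
    out = mann_whitney_u(a, b)
    pooled = np.array(a + b)
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    u_eff = max(u_obs, n_a * len(b) - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        aa = pooled[list(idx)]
        bb = np.delete(pooled, list(idx))
        u = sum(1 for x in aa for y in bb if x > y)
        if max(u, n_a * len(b) - u) >= u_eff:
            count += 1
        total += 1
    assert out["p"] == pytest.approx(count / total, rel=1e-9)


def test_mann_whitney_symmetric_in_sample_order():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.3, 1, 25)
    assert mann_whitney_u(a, b)["p"] == pytest.approx(mann_whitney_u(b, a)["p"])


def _entrant_frame(entrants):
    return pd.DataFrame({"occasion": range(len(entrants)), "entrants": entrants})


def test_protandry_identical_series_zero_offset():
    e = _entrant_frame([5.0, 10.0, 20.0, 10.0, 5.0])
    assert protandry_index(e, e.copy()) == pytest.approx(0.0)


def test_protandry_constructed_shift():
    base = np.array([0.0, 0, 5, 10, 20, 10, 5, 0, 0, 0, 0, 0, 0])
    males = _entrant_frame(base)
    females = _entrant_frame(np.roll(base, 5))
    assert protandry_index(males, females) == pytest.approx(5.0, abs=0.3)


def test_protandry_flat_recruitment_flagged():
    zero = _entrant_frame([0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="recruitment"):
        protandry_index(zero, zero.copy())


def test_null_simulation_p_values_roughly_uniform():
    """Under no group difference the U-test p-value has no mass pile-up at 0."""
    rng = np.random.default_rng(11)
    ps = [mann_whitney_u(rng.normal(0, 1, 15), rng.normal(0, 1, 15))["p"]
          for _ in range(200)]
    assert np.mean(np.array(ps) < 0.2) < 0.35
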