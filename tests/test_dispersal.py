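import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrrkit.dispersal import (
    DispersalKernel,
    displacement_table,
    displacement_summary,
    distance_time_regression,
    extrapolate_proportion,
    fit_kernel,
    inverse_cumulative_table,
    project_to_plane,
    select_best_fit,
)
from mrrkit.events import CaptureEvent

from conftest import day

LAT0, LON0 = 52.5, 14.07
M_PER_DEG_LAT = 111_195.0


def _event_at(iid, k, x_m, y_m, sex="male"):
    """Place an event x_m east / y_m north of the reference point."""
    lat = LAT0 + y_m / M_PER_DEG_LAT
    lon = LON0 + x_m / (M_PER_DEG_LAT * math.cos(math.radians(LAT0)))
    return CaptureEvent(iid, day(k), sex, lat=lat, lon=lon)


def test_projection_identical_points():
    xy = project_to_plane([52.5, 52.5], [14.07, 14.07])
    assert np.linalg.norm(xy[0] - xy[1]) == 0.0


def test_projection_matches_geodesic_scale():
    # 0.001 degrees of latitude is ~111.2 m on the sphere
    xy = project_to_plane([52.5, 52.501], [14.07, 14.07])
    d = np.linalg.norm(xy[1] - xy[0])
    assert d == pytest.approx(111.2, abs=0.1)


def test_projection_translation_invariant():
    lat = np.array([52.5, 52.502, 52.501])
    lon = np.array([14.07, 14.072, 14.069])
    d1 = np.linalg.norm(np.diff(project_to_plane(lat, lon), axis=0), axis=1)
    d2 = np.linalg.norm(np.diff(project_to_plane(lat + 0.01, lon - 0.02), axis=0), axis=1)
    assert np.allclose(d1, d2, rtol=1e-3)  # re-centering distortion < 0.1%


def test_projection_rejects_implausible_coordinates():
    with pytest.raises(ValueError):
        project_to_plane([95.0], [0.0])


def test_displacement_345_triangle():
    evs = [_event_at("a", 0, 0, 0), _event_at("a", 1, 30, 40)]
    rec = displacement_table(evs)
    assert rec.loc[0, "displacement_m"] == pytest.approx(50.0, rel=1e-3)
    assert rec.loc[0, "days_elapsed"] == 1


def test_lifespan_is_segment_sum():
    evs = [
        _event_at("a", 0, 0, 0),
        _event_at("a", 1, 30, 40),
        _event_at("a", 3, 30, 140),
    ]
    rec = displacement_table(evs)
    assert rec.loc[0, "lifespan_m"] == pytest.approx(150.0, rel=1e-3)
    assert rec.loc[0, "displacement_m"] == pytest.approx(50.0, rel=1e-3)
    assert rec.loc[0, "max_displacement_m"] == pytest.approx(
        math.hypot(30, 140), rel=1e-3
    )
    assert rec.loc[0, "lifespan_days"] == 3


def test_single_capture_individuals_absent():
    evs = [_event_at("a", 0, 0, 0), _event_at("b", 0, 10, 10), _event_at("b", 1, 20, 10)]
    rec = displacement_table(evs)
    assert rec["individual_id"].tolist() == ["b"]


def test_inverse_cumulative_direct_count():
    tab = inverse_cumulative_table([10.0, 30.0, 60.0], 50.0)
    assert tab["class_low"].tolist() == [0.0, 50.0]
    assert tab["proportion"].tolist() == [1.0, pytest.approx(1 / 3)]


def test_first_class_proportion_is_one():
    rng = np.random.default_rng(0)
    tab = inverse_cumulative_table(rng.exponential(80, 200), 20.0)
    assert tab["proportion"].iloc[0] == 1.0


def test_scale_equivariance():
    d = np.array([10.0, 30.0, 60.0, 200.0])
    t1 = inverse_cumulative_table(d, 50.0)
    t2 = inverse_cumulative_table(2 * d, 100.0)
    assert np.allclose(t1["proportion"], t2["proportion"])


@given(st.lists(st.floats(min_value=0.0, max_value=5000.0), min_size=1, max_size=60),
       st.sampled_from([20.0, 30.0, 50.0]))
@settings(max_examples=50, deadline=None)
def test_inverse_cumulative_monotone_nonincreasing(distances, width):
    tab = inverse_cumulative_table(distances, width)
    prop = tab["proportion"].to_numpy()
    assert np.all(np.diff(prop) <= 1e-12)
    assert prop[0] == 1.0
    assert np.all((prop >= 0) & (prop <= 1))


def _exact_table(kind, width=50.0, n_classes=6, **params):
    mids = np.arange(n_classes) * width + width / 2
    if kind == "NEF":
        I = params["a"] * np.exp(-params["k"] * mids)
    else:
        I = params["c"] * mids ** -params["n"]
    return pd.DataFrame(
        {"class_low": mids - width / 2, "class_mid": mids, "proportion": I,
         "interval_width": width}
    )


def test_noiseless_nef_recovery():
    fit = fit_kernel(_exact_table("NEF", a=1.0, k=0.01), "NEF")
    assert fit.a_ == pytest.approx(1.0, rel=1e-9)
    assert fit.k_ == pytest.approx(0.01, rel=1e-9)
    assert fit.r2_ == pytest.approx(1.0, abs=1e-12)


def test_noiseless_ipf_recovery():
    fit = fit_kernel(_exact_table("IPF", c=5.0, n=1.3), "IPF")
    assert fit.c_ == pytest.approx(5.0, rel=1e-9)
    assert fit.n_ == pytest.approx(1.3, rel=1e-9)
    assert fit.r2_ == pytest.approx(1.0, abs=1e-12)


def test_two_usable_classes_refused():
    tab = _exact_table("NEF", a=1.0, k=0.01, n_classes=4)
    tab.loc[2:, "proportion"] = 0.0
    with pytest.raises(ValueError, match=">= 3"):
        fit_kernel(tab, "NEF")


def test_select_best_fit_dominant_width():
    rng = np.random.default_rng(1)
    d = rng.exponential(100, 400)
    res = select_best_fit(d)
    assert set(res["grid"]["kind"]) == {"NEF", "IPF"}
    assert len(res["grid"]) == 6
    for kind, fit in res["best"].items():
        sub = res["grid"][res["grid"]["kind"] == kind]
        assert fit.r2_ == pytest.approx(sub["r2"].max())


def test_r2_invariant_to_record_order():
    rng = np.random.default_rng(2)
    d = rng.exponential(100, 300)
    g1 = select_best_fit(d)["grid"]
    g2 = select_best_fit(d[::-1])["grid"]
    assert np.allclose(g1["r2"], g2["r2"])


def test_flat_kernel_extrapolates_constant():
    fit = DispersalKernel("NEF")
    fit.a_, fit.k_, fit.r2_ = 0.5, 0.0, 1.0
    out = extrapolate_proportion(fit)
    assert np.allclose(out["percent"], 50.0)


def test_ipf_power_law_scaling():
    # I(100 m) = 10% with n=1 implies I(1000 m) = 1%
    fit = DispersalKernel("IPF")
    fit.c_, fit.n_, fit.r2_ = 0.1 * 100, 1.0, 1.0
    assert float(fit.predict(100.0)) == pytest.approx(0.10)
    out = extrapolate_proportion(fit, [1000.0])
    assert out["percent"].iloc[0] == pytest.approx(1.0)


def test_extrapolation_monotone_decreasing():
    for kind, params in (("NEF", {"a": 1.0, "k": 0.004}), ("IPF", {"c": 8.0, "n": 1.2})):
        fit = fit_kernel(_exact_table(kind, **params), kind)
        pct = extrapolate_proportion(fit)["percent"].to_numpy()
        assert np.all(np.diff(pct) < 0)


def test_ipf_dominates_nef_at_long_range():
    """Power-law tails sit above exponential tails fitted to heavy-tailed data."""
    rng = np.random.default_rng(3)
    d = 20.0 * (1 - rng.random(500)) ** (-1 / 1.8)  # Pareto displacements
    res = select_best_fit(d)
    nef = extrapolate_proportion(res["best"]["NEF"], [3000.0, 5000.0])
    ipf = extrapolate_proportion(res["best"]["IPF"], [3000.0, 5000.0])
    assert (ipf["percent"].to_numpy() >= nef["percent"].to_numpy()).all()


def test_distance_time_regression_exact_line():
    rec = pd.DataFrame(
        {"days_elapsed": [1, 2, 3, 4], "displacement_m": [10.0, 20.0, 30.0, 40.0]}
    )
    out = distance_time_regression(rec)
    assert out["slope"] == pytest.approx(10.0)
    assert out["r2"] == pytest.approx(1.0)


def test_distance_time_regression_null_slope():
    rng = np.random.default_rng(4)
    rec = pd.DataFrame(
        {"days_elapsed": rng.integers(1, 10, 200),
         "displacement_m": rng.exponential(100, 200)}
    )
    out = distance_time_regression(rec)
    assert out["p"] > 0.01
    assert abs(out["slope"]) < 10.0


def test_distance_time_regression_guards():
    rec = pd.DataFrame({"days_elapsed": [1, 1, 1], "displacement_m": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="variance"):
        distance_time_regression(rec)
    with pytest.raises(ValueError, match=">= 3"):
        distance_time_regression(rec.head(2))


def test_summary_reports_sexes_and_total():
    evs = [
        _event_at("a", 0, 0, 0), _event_at("a", 1, 30, 40),
        _event_at("b", 0, 0, 0, sex="female"), _event_at("b", 2, 0, 100, sex="female"),
    ]
    summ = displacement_summary(displacement_table(evs))
    assert summ["group"].tolist() == ["male", "female", "total"]
    total = summ.set_index("group").loc["total"]
    assert total["mean_m"] == pytest.approx(75.0, rel=1e-3)
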