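import dataclasses
import datetime as dt

import numpy as np
import pytest

from mrrkit.dispersal import displacement_table, select_best_fit
from mrrkit.events import build_encounter_histories, write_events
from mrrkit.popan.likelihood import prob_never_detected
from mrrkit.simulate import (
    GroupScenario,
    SimulationScenario,
    discretized_entry,
    get_preset,
    scenario_presets,
    simulate_mrr,
)


def _uniform_scenario(n=200, K=10, phi=0.85, p=0.4, seed=0, **group_kw):
    return SimulationScenario(
        k_occasions=K,
        groups={"male": GroupScenario(n_super=n, pent=discretized_entry(K, "uniform"),
                                      phi=phi, p=p, **group_kw)},
        seed=seed,
    )


def test_fixed_seed_is_byte_identical(tmp_path):
    sc = get_preset("gen1-like", seed=42)
    e1, t1 = simulate_mrr(sc)
    e2, t2 = simulate_mrr(get_preset("gen1-like", seed=42))
    assert e1 == e2 and t1 == t2
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_events(e1, p1)
    write_events(e2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    e3, _ = simulate_mrr(get_preset("gen1-like", seed=43))
    assert e3 != e1


def test_deterministic_world_everyone_detected_daily():
    K = 6
    pent = np.zeros(K)
    pent[0] = 1.0
    sc = SimulationScenario(
        k_occasions=K,
        groups={"male": GroupScenario(n_super=50, pent=pent, phi=1.0, p=1.0)},
        seed=1,
    )
    events, truth = simulate_mrr(sc)
    assert len(events) == 50 * K
    assert truth["groups"]["male"]["n_detected"] == 50
    hist = build_encounter_histories(events)
    assert np.all(hist.histories == 1)


def test_marked_count_within_binomial_envelope():
    """Observed marked count stays inside the 99% envelope of its analytic
    inclusion probability."""
    K, n = 20, 300
    pent = discretized_entry(K, "beta", 3.0, 3.0)
    phi = np.full(K - 1, 0.8)
    p = np.full(K, 0.4)
    p_incl = 1.0 - prob_never_detected(pent, phi, p)
    marked = []
    for seed in range(10):
        sc = SimulationScenario(
            k_occasions=K,
            groups={"male": GroupScenario(n_super=n, pent=pent, phi=0.8, p=0.4)},
            seed=seed,
        )
        _, truth = simulate_mrr(sc)
        marked.append(truth["groups"]["male"]["n_detected"])
    mu = n * p_incl
    sd = np.sqrt(n * p_incl * (1 - p_incl))
    assert all(abs(m - mu) < 2.576 * sd for m in marked)


def test_large_n_rates_converge_to_expectations():
    """Law-of-large-numbers check at N=5000 (2% tolerance)."""
    K, n = 10, 5000
    pent = discretized_entry(K, "uniform")
    phi = np.full(K - 1, 0.85)
    p = np.full(K, 0.4)
    sc = _uniform_scenario(n=n, K=K, phi=0.85, p=0.4, seed=3)
    events, truth = simulate_mrr(sc)
    p_incl = 1.0 - prob_never_detected(pent, phi, p)
    assert truth["groups"]["male"]["n_detected"] == pytest.approx(n * p_incl, rel=0.02)
    # mean events per individual: expected detections per superpop member
    e_det = 0.0
    for b in range(K):
        # expected occasions alive from entry b
        alive = np.cumprod(np.concatenate([[1.0], phi[b:]]))
        e_det += pent[b] * p[0] * alive[: K - b].sum()
    assert len(events) / n == pytest.approx(e_det, rel=0.02)


def test_single_step_displacements_match_kernel():
    """phi=p=1 over two occasions: displacement is exactly one kernel step."""
    K = 2
    pent = np.array([1.0, 0.0])
    sc = SimulationScenario(
        k_occasions=K,
        groups={"male": GroupScenario(n_super=5000, pent=pent, phi=1.0, p=1.0,
                                      step_mean_m=100.0)},
        seed=4,
    )
    events, _ = simulate_mrr(sc)
    rec = displacement_table(events)
    assert len(rec) == 5000
    assert rec["displacement_m"].mean() == pytest.approx(100.0, rel=0.02)


def test_exponential_steps_recover_nef_constant():
    """Fitted NEF decay rate within 15% of the generating 1/mean."""
    K = 2
    pent = np.array([1.0, 0.0])
    sc = SimulationScenario(
        k_occasions=K,
        groups={"male": GroupScenario(n_super=500, pent=pent, phi=1.0, p=1.0,
                                      step_mean_m=100.0)},
        seed=5,
    )
    events, _ = simulate_mrr(sc)
    rec = displacement_table(events)
    res = select_best_fit(rec, (20.0,))
    k_hat = res["best"]["NEF"].k_
    assert k_hat == pytest.approx(0.01, rel=0.15)


def test_wing_scores_valid_and_increasing_with_age():
    events, truth = simulate_mrr(_uniform_scenario(n=400, K=12, seed=6,
                                                   wing_wear_rate=0.3))
    scores = np.array([e.wing_score for e in events])
    assert np.all((scores >= 1) & (scores <= 4))
    entry = {f"1M{i:04d}": b for i, b in enumerate(truth["groups"]["male"]["entries"])}
    day0 = min(e.date for e in events)
    ages, ss = [], []
    for e in events:
        ages.append((e.date - day0).days - entry[e.individual_id])
        ss.append(e.wing_score)
    ages, ss = np.array(ages), np.array(ss, dtype=float)
    assert ss[ages >= 6].mean() > ss[ages <= 1].mean()


def test_nectar_only_when_nectaring():
    events, _ = simulate_mrr(get_preset("gen2-like", seed=7))
    for e in events:
        assert (e.nectar_genus is not None) == (e.behaviour == "nectaring")


def test_presets_match_study_magnitudes():
    presets = scenario_presets()
    g1 = presets["gen1-like"]
    assert g1.k_occasions == 21
    assert (g1.groups["male"].n_super, g1.groups["female"].n_super) == (155, 155)
    # protandrous: female entry mass sits later than male
    t = np.arange(21)
    shift = g1.groups["female"].pent @ t - g1.groups["male"].pent @ t
    assert shift > 2.0
    g2 = presets["gen2-like"]
    assert g2.k_occasions == 28
    assert (g2.groups["male"].n_super, g2.groups["female"].n_super) == (382, 276)
    t2 = np.arange(28)
    assert abs(g2.groups["female"].pent @ t2 - g2.groups["male"].pent @ t2) < 0.5
    assert g2.groups["female"].step_kernel == "powerlaw"


def test_unknown_preset_rejected():
    with pytest.raises(KeyError, match="unknown preset"):
        get_preset("gen3-like")


def test_invalid_scenarios_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        GroupScenario(n_super=10, pent=np.array([0.5, 0.6]))
    with pytest.raises(ValueError, match="occasions"):
        SimulationScenario(
            k_occasions=1,
            groups={"male": GroupScenario(n_super=1, pent=np.array([1.0]))},
        )
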