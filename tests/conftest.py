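import datetime as dt

import numpy as np
import pytest

from mrrkit.events import CaptureEvent, build_encounter_histories
from mrrkit.simulate import (
    GroupScenario,
    SimulationScenario,
    discretized_entry,
    simulate_mrr,
)

D0 = dt.date(2021, 5, 24)


def day(k: int) -> dt.date:
    return D0 + dt.timedelta(days=k)


@pytest.fixture
def tiny_events():
    """Three individuals, five occasions, hand-checkable."""
    mk = lambda i, k, sex, **kw: CaptureEvent(i, day(k), sex, lat=52.5, lon=14.07, **kw)
    return [
        mk("a", 0, "male", behaviour="flying", wing_score=1),
        mk("a", 2, "male", behaviour="resting", wing_score=2),
        mk("b", 0, "female", behaviour="nectaring", nectar_genus="Knautia", wing_score=1),
        mk("b", 1, "female", behaviour="flying", wing_score=1),
        mk("b", 4, "female", behaviour="basking", wing_score=3),
        mk("c", 3, "male", behaviour="flying", wing_score=2),
    ]


@pytest.fixture(scope="session")
def recovery_scenario():
    """The parameter-recovery world: K=20, N=300 per sex, phi=0.8, p=0.4,
    beta-shaped entry."""
    K = 20
    pent = discretized_entry(K, "beta", 3.0, 3.0)
    return SimulationScenario(
        k_occasions=K,
        groups={
            "male": GroupScenario(n_super=300, pent=pent, phi=0.8, p=0.4),
            "female": GroupScenario(n_super=300, pent=pent, phi=0.8, p=0.4),
        },
        seed=0,
    )


@pytest.fixture(scope="session")
def sim_events(recovery_scenario):
    events, truth = simulate_mrr(recovery_scenario)
    return events, truth


@pytest.fixture(scope="session")
def sim_histories(sim_events):
    events, _ = sim_events
    return build_encounter_histories(events)
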