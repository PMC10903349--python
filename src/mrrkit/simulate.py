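"""Seeded synthetic mark-release-recapture worlds.

The generator emulates the statistical structure the analysis pipeline
assumes: an open population with per-occasion entry (pent), daily survival
(phi) and detection (p), possibly sex-structured; memoryless per-day
movement with a configurable step-length kernel; wing wear increasing with
age; and multinomial behaviour / nectar-genus draws at each capture. Only
detected events are returned; the generating truth is returned separately
(and written to a sealed file by the CLI) so analysis code cannot read it
by accident.

A fixed seed yields byte-identical event tables: one
``numpy.random.Generator`` is threaded through all draws in a documented
order (per group, then per individual: entry, survival, detection, steps,
wing noise, behaviour, nectar genus).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .events import CaptureEvent

__all__ = ["GroupScenario", "SimulationScenario", "simulate_mrr", "scenario_presets",
           "get_preset", "discretized_entry"]

_SITE_CENTER = (52.5, 14.07)  # wet-meadow study landscape in eastern Brandenburg
_M_PER_DEG_LAT = 111_195.0


def discretized_entry(
    K: int, kind: str = "beta", a: float = 2.0, b: float = 2.0,
    peak: float | None = None, width: float | None = None, shift: float = 0.0,
) -> np.ndarray:
    """Entry-probability vector over K occasions.

    ``beta``: Beta(a, b) density discretized over the season;
    ``logistic_peak``: discretized logistic density centered at ``peak``
    days with scale ``width``; ``uniform``: equal entry. ``shift`` moves
    the distribution right by that many days (used for protandry: shift
    females late relative to males).
    """
    t = np.arange(K, dtype=float)
    if kind == "uniform":
        w = np.ones(K)
    elif kind == "beta":
        x = (t - shift + 0.5) / K
        x = np.clip(x, 1e-9, 1 - 1e-9)
        w = stats.beta.pdf(x, a, b)
    elif kind == "logistic_peak":
        mu = (peak if peak is not None else K / 3) + shift
        s = width if width is not None else K / 8
        w = stats.logistic.pdf(t, loc=mu, scale=s)
    else:
        raise ValueError(f"unknown entry kind {kind!r}")
    w = np.clip(w, 1e-12, None)
    return w / w.sum()


@dataclass
class GroupScenario:
    """Generative parameters for one sex."""

    n_super: int
    pent: np.ndarray
    phi: float | np.ndarray = 0.8
    p: float | np.ndarray = 0.4
    step_kernel: str = "exponential"  # or "powerlaw"
    step_mean_m: float = 100.0  # exponential mean step length
    step_pareto_shape: float = 1.8  # powerlaw tail exponent (>1)
    step_min_m: float = 10.0  # powerlaw scale / minimum step
    wing_wear_rate: float = 0.25  # expected score increase per day alive
    behaviour_probs: dict[str, float] = field(
        default_factory=lambda: {
            "flying": 0.45, "nectaring": 0.2, "resting": 0.15,
            "basking": 0.12, "ovipositing": 0.03, "interacting": 0.05,
        }
    )
    nectar_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Knautia": 0.5, "Cardamine": 0.2, "Lychnis": 0.15,
            "Myosotis": 0.1, "Cirsium": 0.05,
        }
    )

    def __post_init__(self) -> None:
        self.pent = np.asarray(self.pent, dtype=float)
        if self.n_super < 0:
            raise ValueError("n_super must be >= 0")
        if self.pent.size == 0:
            raise ValueError("pent must cover at least one occasion")
        if not math.isclose(self.pent.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("pent must sum to 1")
        for name, probs in (("behaviour", self.behaviour_probs), ("nectar", self.nectar_probs)):
            s = sum(probs.values())
            if not math.isclose(s, 1.0, rel_tol=1e-9):
                raise ValueError(f"{name} probabilities must sum to 1 (got {s})")

    def rates(self, K: int) -> tuple[np.ndarray, np.ndarray]:
        phi = np.broadcast_to(np.asarray(self.phi, dtype=float), (K - 1,)).copy()
        p = np.broadcast_to(np.asarray(self.p, dtype=float), (K,)).copy()
        if np.any((phi < 0) | (phi > 1)) or np.any((p < 0) | (p > 1)):
            raise ValueError("phi and p must lie in [0, 1]")
        return phi, p


@dataclass
class SimulationScenario:
    """A complete synthetic MRR study (both sexes, one generation)."""

    k_occasions: int
    groups: dict[str, GroupScenario]
    generation: int = 1
    start_date: dt.date = dt.date(2021, 5, 24)
    site_center: tuple[float, float] = _SITE_CENTER
    site_extent_m: float = 600.0  # initial positions uniform in this square
    effort: np.ndarray | None = None  # per-occasion detection multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_occasions < 2:
            raise ValueError("need at least 2 occasions")
        for g in self.groups.values():
            if g.pent.size != self.k_occasions:
                raise ValueError("pent length must equal k_occasions")
        if self.effort is not None:
            self.effort = np.asarray(self.effort, dtype=float)
            if self.effort.size != self.k_occasions:
                raise ValueError("effort length must equal k_occasions")
            if np.any(self.effort < 0):
                raise ValueError("effort must be >= 0")

    @property
    def occasions(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=k) for k in range(self.k_occasions)]


def _step_length(g: GroupScenario, rng: np.random.Generator) -> float:
    if g.step_kernel == "exponential":
        return float(rng.exponential(g.step_mean_m))
    if g.step_kernel == "powerlaw":
        # Pareto: survival (x/xm)^-shape, heavy tail for shape <~ 2
        return float(g.step_min_m * (1.0 - rng.random()) ** (-1.0 / g.step_pareto_shape))
    raise ValueError(f"unknown step kernel {g.step_kernel!r}")


def simulate_mrr(scenario: SimulationScenario) -> tuple[list[CaptureEvent], dict]:
    """Simulate one MRR study; returns (detected events, truth record)."""
    rng = np.random.default_rng(scenario.seed)
    K = scenario.k_occasions
    occ = scenario.occasions
    lat0, lon0 = scenario.site_center
    m_per_deg_lon = _M_PER_DEG_LAT * math.cos(math.radians(lat0))
    half = scenario.site_extent_m / 2.0
    eff = scenario.effort if scenario.effort is not None else np.ones(K)
    eff_mult = eff / eff.mean() if eff.mean() > 0 else np.ones(K)
    events: list[CaptureEvent] = []
    truth: dict = {
        "seed": scenario.seed,
        "k_occasions": K,
        "generation": scenario.generation,
        "groups": {},
    }
    for sex in sorted(scenario.groups):
        g = scenario.groups[sex]
        phi, p = g.rates(K)
        beh_names = list(g.behaviour_probs)
        beh_p = np.array([g.behaviour_probs[b] for b in beh_names])
        nec_names = list(g.nectar_probs)
        nec_p = np.array([g.nectar_probs[b] for b in nec_names])
        entries, deaths = [], []
        n_detected = 0
        for i in range(g.n_super):
            iid = f"{scenario.generation}{sex[0].upper()}{i:04d}"
            b = int(rng.choice(K, p=g.pent))
            x = float(rng.uniform(-half, half))
            y = float(rng.uniform(-half, half))
            death = K  # index of first occasion the individual is dead on
            detected_any = False
            wing_noise = float(rng.normal(0.0, 0.35))
            for t in range(b, K):
                if t > b:
                    if rng.random() >= phi[t - 1]:
                        death = t
                        break
                    step = _step_length(g, rng)
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    x += step * math.cos(theta)
                    y += step * math.sin(theta)
                p_det = min(p[t] * eff_mult[t], 1.0)
                if rng.random() < p_det:
                    detected_any = True
                    age = t - b
                    score = int(np.clip(1 + math.floor(g.wing_wear_rate * age + wing_noise + 0.5), 1, 4))
                    beh = str(rng.choice(beh_names, p=beh_p))
                    genus = str(rng.choice(nec_names, p=nec_p)) if beh == "nectaring" else None
                    events.append(
                        CaptureEvent(
                            individual_id=iid,
                            date=occ[t],
                            sex=sex,
                            lat=lat0 + y / _M_PER_DEG_LAT,
                            lon=lon0 + x / m_per_deg_lon,
                            behaviour=beh,
                            wing_score=score,
                            nectar_genus=genus,
                            generation=scenario.generation,
                        )
                    )
            entries.append(b)
            deaths.append(death)
            n_detected += int(detected_any)
        truth["groups"][sex] = {
            "n_super": g.n_super,
            "pent": g.pent.tolist(),
            "phi": phi.tolist(),
            "p": p.tolist(),
            "step_kernel": g.step_kernel,
            "step_mean_m": g.step_mean_m,
            "step_pareto_shape": g.step_pareto_shape,
            "wing_wear_rate": g.wing_wear_rate,
            "entries": entries,
            "deaths": deaths,
            "n_detected": n_detected,
        }
    events.sort(key=lambda e: (e.individual_id, e.date))
    return events, truth


def scenario_presets() -> dict[str, SimulationScenario]:
    """Named scenarios mirroring the magnitudes of a two-generation study.

    ``gen1-like``: 21 occasions, 155 individuals per sex, protandrous entry
    (female peak ~4 days after males), moderate detection, exponential
    steps. ``gen2-like``: 28 occasions, 382 males / 276 females,
    synchronous entry, lower detection, heavier-tailed female step kernel.
    These are pastiches of the study conditions, not data.
    """
    presets: dict[str, SimulationScenario] = {}
    K1 = 21
    presets["gen1-like"] = SimulationScenario(
        k_occasions=K1,
        generation=1,
        start_date=dt.date(2021, 5, 24),
        groups={
            "male": GroupScenario(
                n_super=155,
                pent=discretized_entry(K1, "logistic_peak", peak=6.0, width=2.5),
                phi=0.8,
                p=0.45,
                step_mean_m=60.0,
                wing_wear_rate=0.3,
            ),
            "female": GroupScenario(
                n_super=155,
                pent=discretized_entry(K1, "logistic_peak", peak=6.0, width=2.5, shift=4.0),
                phi=0.8,
                p=0.35,
                step_mean_m=90.0,
                wing_wear_rate=0.3,
                behaviour_probs={
                    "flying": 0.35, "nectaring": 0.25, "resting": 0.15,
                    "basking": 0.12, "ovipositing": 0.08, "interacting": 0.05,
                },
            ),
        },
        seed=0,
    )
    K2 = 28
    nectar2 = {"Lythrum": 0.45, "Cirsium": 0.25, "Knautia": 0.1, "Mentha": 0.1, "Eupatorium": 0.1}
    presets["gen2-like"] = SimulationScenario(
        k_occasions=K2,
        generation=2,
        start_date=dt.date(2021, 7, 14),
        groups={
            "male": GroupScenario(
                n_super=382,
                pent=discretized_entry(K2, "logistic_peak", peak=9.0, width=4.0),
                phi=0.75,
                p=0.25,
                step_mean_m=60.0,
                wing_wear_rate=0.12,
                nectar_probs=nectar2,
            ),
            "female": GroupScenario(
                n_super=276,
                pent=discretized_entry(K2, "logistic_peak", peak=9.0, width=4.0),
                phi=0.75,
                p=0.18,
                step_kernel="powerlaw",
                step_pareto_shape=1.6,
                step_min_m=25.0,
                wing_wear_rate=0.05,
                behaviour_probs={
                    "flying": 0.25, "nectaring": 0.3, "resting": 0.25,
                    "basking": 0.1, "ovipositing": 0.05, "interacting": 0.05,
                },
                nectar_probs=nectar2,
            ),
        },
        seed=0,
    )
    return presets


def get_preset(name: str, seed: int | None = None, **overrides) -> SimulationScenario:
    """Fetch a preset by name, optionally reseeded."""
    presets = scenario_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    sc = presets[name]
    if seed is not None:
        sc = dataclasses.replace(sc, seed=seed)
    if overrides:
        sc = dataclasses.replace(sc, **overrides)
    return sc
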