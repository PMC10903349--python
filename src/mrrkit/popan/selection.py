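"""Model ranking by QAICc, model averaging, and dispersion (c-hat) estimation.

QAICc adjusts the small-sample AICc for over/under-dispersion with a
variance-inflation factor c-hat:

    QAICc = (-2 lnL) / c-hat + 2 K + 2 K (K + 1) / (n_eff - K - 1)

Akaike weights over a candidate set are w_i = exp(-d_i/2) / sum_j
exp(-d_j/2) with d_i the QAICc difference to the best model; the model
likelihood is exp(-d_i/2). Model-averaged estimates use the weights with
Buckland's unconditional standard error.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from ..events import EncounterHistorySet
from .estimator import PopanEstimator
from .likelihood import pack_histories, popan_negative_log_likelihood

__all__ = [
    "qaicc",
    "model_table",
    "model_average_abundance",
    "estimate_chat",
    "simulate_histories_from_params",
]


def qaicc(loglik: float, k_params: int, chat: float, n_eff: int) -> float:
    """c-hat-adjusted small-sample AIC."""
    if chat <= 0:
        raise ValueError("chat must be positive")
    if n_eff <= k_params + 1:
        raise ValueError(
            f"n_eff={n_eff} too small for K={k_params} (correction undefined)"
        )
    return (
        -2.0 * loglik / chat
        + 2.0 * k_params
        + 2.0 * k_params * (k_params + 1) / (n_eff - k_params - 1)
    )


def _common_signature(fits) -> None:
    sigs = {f._signature for f in fits}
    if len(sigs) > 1:
        raise ValueError("model table requires fits on a common dataset")


def model_table(fits, chat: float | None = None) -> pd.DataFrame:
    """Rank fitted models by QAICc (ascending) with weights.

    If ``chat`` is given it overrides each fit's own value so the whole
    table is adjusted consistently (the usual practice: one c-hat from the
    most general model, applied to all candidates).
    """
    if not fits:
        raise ValueError("no fits supplied")
    _common_signature(fits)
    rows = []
    for f in fits:
        c = chat if chat is not None else f.chat_used_
        rows.append(
            {
                "model": f.spec_.label(),
                "qaicc": qaicc(f.loglik_, f.n_params_, c, f.n_eff_),
                "n_par": f.n_params_,
                "chat": c,
                "loglik": f.loglik_,
                "_fit": f,
            }
        )
    df = pd.DataFrame(rows).sort_values("qaicc", kind="stable").reset_index(drop=True)
    df["delta_qaicc"] = df["qaicc"] - df["qaicc"].iloc[0]
    rel = np.exp(-df["delta_qaicc"] / 2.0)
    df["model_likelihood"] = rel
    df["qaicc_weight"] = rel / rel.sum()
    cols = ["model", "qaicc", "delta_qaicc", "qaicc_weight", "model_likelihood", "n_par", "chat", "loglik", "_fit"]
    return df[cols]


def model_average_abundance(
    fits,
    weights: np.ndarray | None = None,
    subset: int | None = None,
    chat: float | None = None,
) -> dict:
    """Weighted average of superpopulation and daily abundance estimates.

    ``subset`` keeps the best ``subset`` models by QAICc before
    renormalizing the weights. Unconditional SEs follow Buckland:
    se = sum_i w_i sqrt(var_i + (theta_i - theta_bar)^2).
    """
    tab = model_table(fits, chat=chat)
    if subset is not None:
        if subset < 1:
            raise ValueError("subset must keep at least one model")
        tab = tab.head(subset).copy()
    w = (
        np.asarray(weights, dtype=float)
        if weights is not None
        else tab["qaicc_weight"].to_numpy()
    )
    if w.size != len(tab) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("invalid weights")
    w = w / w.sum()
    sel = list(tab["_fit"])
    groups = sel[0].group_names_
    nhat = np.array([f.nhat_ for f in sel])  # (M, G)
    nse = np.array([f.nhat_se_ for f in sel])
    nbar = w @ nhat
    n_unc = np.einsum("m,mg->g", w, np.sqrt(nse**2 + (nhat - nbar) ** 2))
    frames = [f.derived_abundance(require_convergence=False) for f in sel]
    base = frames[0][["group", "occasion", "date"]].copy()
    ab = np.array([fr["abundance"].to_numpy() for fr in frames])
    se = np.array([fr["se"].to_numpy() for fr in frames])
    abar = w @ ab
    aunc = np.einsum("m,mt->t", w, np.sqrt(se**2 + (ab - abar) ** 2))
    daily = base.assign(abundance=abar, se=aunc)
    return {
        "weights": w,
        "models": [f.spec_.label() for f in sel],
        "groups": groups,
        "nhat": nbar,
        "nhat_se": n_unc,
        "daily": daily,
    }


# -- dispersion --------------------------------------------------------------


def _saturated_loglik(packed) -> float:
    """Conditional multinomial saturated log-likelihood over observed histories."""
    ll = 0.0
    for c, n in zip(packed.counts, packed.n_observed):
        ll += float(np.sum(c * np.log(c / n)))
    return ll


def deviance(fit: PopanEstimator) -> float:
    """2 * (saturated conditional lnL - model lnL) on the fitted data."""
    return 2.0 * (_saturated_loglik(fit._packed) - fit.loglik_)


def simulate_histories_from_params(
    phi: np.ndarray,
    p: np.ndarray,
    pent: np.ndarray,
    N: np.ndarray,
    group_names,
    rng: np.random.Generator,
    occasions=None,
) -> EncounterHistorySet:
    """Generate detected encounter histories from POPAN parameters.

    Arrays are (G, K-1), (G, K), (G, K) and (G,); undetected individuals
    are discarded, matching what a field study observes.
    """
    G, K = p.shape
    rows, grs, ids = [], [], []
    for gi in range(G):
        n = int(round(N[gi]))
        entries = rng.choice(K, size=n, p=pent[gi])
        for i in range(n):
            alive = True
            h = np.zeros(K, dtype=np.int8)
            for t in range(entries[i], K):
                if t > entries[i]:
                    alive = alive and (rng.random() < phi[gi, t - 1])
                if not alive:
                    break
                if rng.random() < p[gi, t]:
                    h[t] = 1
            if h.any():
                rows.append(h)
                grs.append(group_names[gi])
                ids.append(f"{group_names[gi]}-{gi}-{i:05d}")
    if not rows:
        raise RuntimeError("simulation produced no detected individuals")
    occ = (
        list(occasions)
        if occasions is not None
        else [dt.date(2000, 1, 1) + dt.timedelta(days=k) for k in range(K)]
    )
    return EncounterHistorySet(occ, np.asarray(rows), ids, np.asarray(grs, dtype=object))


def estimate_chat(
    fit: PopanEstimator,
    histories: EncounterHistorySet | None = None,
    method: str = "bootstrap",
    B: int = 100,
    seed: int | None = None,
    manual: float | None = None,
    effort: np.ndarray | None = None,
) -> float:
    """Dispersion factor c-hat from the most general fitted model.

    ``bootstrap``: parametric bootstrap -- simulate B datasets from the
    fitted model, refit, and divide the observed deviance by the mean
    simulated deviance. ``deviance_df``: observed deviance over its
    degrees of freedom (n_eff - K). ``manual``: pass-through of a value
    computed elsewhere.
    """
    if method == "manual":
        if manual is None or manual <= 0:
            raise ValueError("manual c-hat must be a positive number")
        return float(manual)
    if not fit.converged_:
        raise RuntimeError("general model must converge before estimating c-hat")
    if method == "deviance_df":
        df = fit.n_eff_ - fit.n_params_
        if df <= 0:
            raise ValueError("non-positive degrees of freedom")
        return deviance(fit) / df
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    if B < 20:
        raise ValueError("bootstrap needs B >= 20 replicates")
    rng = np.random.default_rng(seed)
    obs_dev = deviance(fit)
    devs = []
    for _ in range(B):
        sim = simulate_histories_from_params(
            fit.phi_, fit.p_, fit.pent_, fit.nhat_, fit.group_names_, rng,
            occasions=fit.occasions_,
        )
        ref = PopanEstimator(
            formula=fit.spec_,
            n_starts=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(sim, effort=effort)
        devs.append(deviance(ref))
    return float(obs_dev / np.mean(devs))
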