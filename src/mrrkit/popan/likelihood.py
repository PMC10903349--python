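"""Schwarz-Arnason (POPAN) superpopulation likelihood.

The open-population Jolly-Seber model in its superpopulation
parameterization: a group (sex) has N individuals in total, each entering
the study area just before occasion b with probability pent_b
(sum_b pent_b = 1), surviving from occasion j to j+1 with probability
phi_j, and being detected on occasion j (while present) with probability
p_j.

For an observed encounter history with first detection f and last
detection l,

    P(omega) = psi_f * p_f * prod_{j=f+1..l} phi_{j-1} p_j^{w_j} (1-p_j)^{1-w_j}
               * chi_l,

where psi is the probability of being present and not yet detected
(psi_1 = pent_1; psi_{j+1} = psi_j (1-p_j) phi_j + pent_{j+1}) and chi_l
the probability of never being seen after l (chi_K = 1; chi_j = (1-phi_j)
+ phi_j (1-p_{j+1}) chi_{j+1}).

The full likelihood for a group with n observed individuals multiplies the
history probabilities by the binomial term for the N - n members of the
superpopulation that were never detected, whose probability is
P0 = sum_b pent_b xi_b with xi_K = 1-p_K and
xi_j = (1-p_j)((1-phi_j) + phi_j xi_{j+1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["PackedHistories", "pack_histories", "history_log_probs", "prob_never_detected",
           "popan_negative_log_likelihood"]

_BIG = 1e10  # finite penalty signalled to the optimizer on invalid evaluations


@dataclass
class PackedHistories:
    """Unique encounter histories with multiplicities, one block per group."""

    group_names: list[str]
    H: list[np.ndarray]  # per group: (n_unique, K) 0/1
    counts: list[np.ndarray]  # per group: multiplicity of each unique history
    n_observed: np.ndarray  # per group: number of observed individuals
    K: int


def pack_histories(histories) -> PackedHistories:
    """Collapse an :class:`~mrrkit.events.EncounterHistorySet` to unique rows."""
    names = histories.group_names
    Hs, cnts, nobs = [], [], []
    for g in names:
        sub = histories.histories[histories.groups == g]
        uniq, c = np.unique(sub, axis=0, return_counts=True)
        Hs.append(uniq.astype(float))
        cnts.append(c.astype(float))
        nobs.append(sub.shape[0])
    return PackedHistories(names, Hs, cnts, np.asarray(nobs, dtype=float),
                           histories.n_occasions)


def _psi(pent: np.ndarray, phi: np.ndarray, p: np.ndarray) -> np.ndarray:
    K = pent.size
    psi = np.empty(K)
    psi[0] = pent[0]
    for j in range(K - 1):
        psi[j + 1] = psi[j] * (1 - p[j]) * phi[j] + pent[j + 1]
    return psi


def _chi(phi: np.ndarray, p: np.ndarray) -> np.ndarray:
    K = p.size
    chi = np.empty(K)
    chi[-1] = 1.0
    for j in range(K - 2, -1, -1):
        chi[j] = (1 - phi[j]) + phi[j] * (1 - p[j + 1]) * chi[j + 1]
    return chi


def prob_never_detected(pent: np.ndarray, phi: np.ndarray, p: np.ndarray) -> float:
    """P(an in-superpopulation individual is never detected)."""
    K = p.size
    xi = np.empty(K)
    xi[-1] = 1 - p[-1]
    for j in range(K - 2, -1, -1):
        xi[j] = (1 - p[j]) * ((1 - phi[j]) + phi[j] * xi[j + 1])
    return float(np.dot(pent, xi))


def history_log_probs(
    H: np.ndarray, pent: np.ndarray, phi: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Log-probability of each (detected) encounter history row in ``H``."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    K = p.size
    # keep rates strictly inside (0, 1): avoids inf - inf = nan in the
    # cumulative-sum algebra below at a cost of O(1e-12) in the result
    eps = 1e-12
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    phi = np.clip(np.asarray(phi, dtype=float), eps, 1 - eps)
    with np.errstate(divide="ignore"):
        lp = np.log(p)
        lq = np.log1p(-p)
        lphi = np.log(phi)
    psi = _psi(pent, phi, p)
    chi = _chi(phi, p)
    with np.errstate(divide="ignore"):
        lpsi = np.log(psi)
        lchi = np.log(chi)
    # cumulative sums with a leading zero for range differences
    cum_lphi = np.concatenate([[0.0], np.cumsum(lphi)])  # over intervals
    cum_lq = np.concatenate([[0.0], np.cumsum(lq)])  # over occasions
    f = np.argmax(H > 0, axis=1)
    l = K - 1 - np.argmax(H[:, ::-1] > 0, axis=1)
    s_caps = H @ lp  # sum of log p over all detection occasions
    s_caps_q = H @ lq  # sum of log(1-p) over detection occasions
    # intervals f+1..l (1-based) == lphi indices f..l-1 (0-based)
    surv = cum_lphi[l] - cum_lphi[f]
    # non-detection occasions strictly inside (f, l]
    nondet = (cum_lq[l + 1] - cum_lq[f + 1]) - (s_caps_q - lq[f])
    return lpsi[f] + s_caps + surv + nondet + lchi[l]


def popan_negative_log_likelihood(
    beta: np.ndarray, dm, packed: PackedHistories
) -> float:
    """Negative log-likelihood; finite penalty on invalid parameter points."""
    try:
        phi, p, pent, N = dm.natural_parameters(beta)
    except (FloatingPointError, OverflowError):
        return _BIG
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(p)) and np.all(np.isfinite(N))):
        return _BIG
    nll = 0.0
    for gi in range(len(packed.group_names)):
        n = packed.n_observed[gi]
        Ng = N[gi]
        if Ng < n:
            # smooth barrier: evaluate at the feasible edge N = n and add a
            # quadratic push-back so the optimizer sees a gradient, not a cliff
            nll += 100.0 * (n - Ng) ** 2 + 1.0
            Ng = n
        lps = history_log_probs(packed.H[gi], pent[gi], phi[gi], p[gi])
        if not np.all(np.isfinite(lps)):
            return _BIG
        p0 = prob_never_detected(pent[gi], phi[gi], p[gi])
        # p0 == 1 only when p == 0 everywhere, which the history terms already punish
        if p0 <= 0 or p0 >= 1:
            lp0 = -_BIG if p0 <= 0 else 0.0
        else:
            lp0 = np.log(p0)
        binom = gammaln(Ng + 1) - gammaln(Ng - n + 1) - gammaln(n + 1) + (Ng - n) * lp0
        nll -= float(packed.counts[gi] @ lps) + binom
    if not np.isfinite(nll):
        return _BIG
    return nll
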