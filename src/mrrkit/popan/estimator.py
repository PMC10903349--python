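"""Maximum-likelihood fitting of POPAN models.

:class:`PopanEstimator` is a scikit-learn-style estimator: construct it
with a model formula and tuning options, call :meth:`fit` on an
:class:`~mrrkit.events.EncounterHistorySet`, and read the fitted
quantities off trailing-underscore attributes. Standard errors come from
the inverse observed information; derived daily abundances and their
delta-method standard errors are available from
:meth:`derived_abundance`.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .formula import PopanModelSpec, build_design_matrices, parse_model_formula
from .likelihood import (
    PackedHistories,
    pack_histories,
    popan_negative_log_likelihood,
    prob_never_detected,
)

__all__ = ["PopanEstimator", "FitError", "fit_model", "derived_daily_abundance"]


class FitError(RuntimeError):
    """All optimizer starts failed; carries the best diagnostics seen."""


def _data_signature(histories) -> str:
    h = hashlib.sha256()
    h.update(histories.histories.tobytes())
    h.update(",".join(map(str, histories.groups)).encode())
    h.update(",".join(d.isoformat() for d in histories.occasions).encode())
    return h.hexdigest()


class PopanEstimator(BaseEstimator):
    """POPAN Jolly-Seber superpopulation model.

    Parameters
    ----------
    formula : str
        Model structure, e.g. ``"Phi(g+T^2) p(g+t) pent(g*T^2) N(g)"``.
    chat : float
        Variance-inflation factor applied in :attr:`qaicc_`; 1 means the
        ordinary AICc. Values below 1 (underdispersion) are used as-is
        unless ``clamp_chat`` is set.
    clamp_chat : bool
        If True, ``max(chat, 1)`` is used (a common MARK recommendation).
    n_starts : int
        Number of random multi-starts tried after the null warm start.
        Starts stop early once two of them agree on the optimum.
    n_eff : int or None
        Effective sample size for the AICc small-sample correction;
        defaults to the number of marked individuals in the fitted data.
    random_state : int or None
        Seed for the random multi-starts.
    """

    #: gradient-norm threshold (link scale) declaring convergence
    GRAD_TOL = 1e-5

    def __init__(
        self,
        formula: str = "Phi(.) p(.) pent(t) N(.)",
        chat: float = 1.0,
        clamp_chat: bool = False,
        n_starts: int = 5,
        n_eff: int | None = None,
        max_iter: int = 1000,
        random_state: int | None = None,
    ) -> None:
        self.formula = formula
        self.chat = chat
        self.clamp_chat = clamp_chat
        self.n_starts = n_starts
        self.n_eff = n_eff
        self.max_iter = max_iter
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------
    def _start_points(self, dm, packed: PackedHistories, rng) -> list[np.ndarray]:
        n_par = dm.n_params
        base = np.zeros(n_par)
        # warm start: p and phi at their null-ish values, N at twice the count
        sizes = np.cumsum(dm.sizes)
        # crude detection frequency -> logit start for p intercept
        tot_caps = sum(float(c @ h.sum(axis=1)) for c, h in zip(packed.counts, packed.H))
        n_tot = float(packed.n_observed.sum())
        p_bar = min(max(tot_caps / (n_tot * packed.K), 0.05), 0.95)
        base[dm.sizes[0]] = np.log(p_bar / (1 - p_bar))  # p intercept
        i_n = sizes[2]  # first N column (intercept)
        n0 = packed.n_observed[0] if dm.spec.n.group else n_tot / len(packed.group_names)
        base[i_n] = np.log(max(2.0 * n0, 4.0))
        if dm.spec.n.group:
            for gi in range(1, len(packed.group_names)):
                base[i_n + gi] = np.log(max(2.0 * packed.n_observed[gi], 4.0)) - base[i_n]
        starts = [base]
        for _ in range(self.n_starts):
            starts.append(base + rng.normal(0.0, 0.5, size=n_par))
        return starts

    def fit(self, histories, effort: np.ndarray | None = None) -> "PopanEstimator":
        """Fit the model to an encounter-history set by MLE."""
        spec = (
            self.formula
            if isinstance(self.formula, PopanModelSpec)
            else parse_model_formula(self.formula)
        )
        packed = pack_histories(histories)
        groups = packed.group_names
        dm = build_design_matrices(spec, packed.K, groups, effort)
        rng = np.random.default_rng(self.random_state)
        bounds = self._bounds(dm, packed)
        best = None
        n_agree = 0
        attempts = []
        for x0 in self._start_points(dm, packed, rng):
            res = minimize(
                popan_negative_log_likelihood,
                x0,
                args=(dm, packed),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "maxfun": 10 * self.max_iter},
            )
            attempts.append(res)
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun - 1e-6:
                best = res
                n_agree = 1
            elif abs(res.fun - best.fun) <= 1e-4:
                n_agree += 1
                if n_agree >= 2:
                    break
        if best is None or best.fun >= 1e9:
            raise FitError(f"no optimizer start converged; diagnostics: {attempts[-1]}")
        self._finalize(best, spec, dm, packed, histories)
        return self

    @staticmethod
    def _bounds(dm, packed):
        # logit/softmax coefficients kept inside +-15 (rates within ~3e-7 of
        # the boundary); N coefficients wide but finite
        b = [(-15.0, 15.0)] * (dm.sizes[0] + dm.sizes[1] + dm.sizes[2])
        n_tot = max(packed.n_observed.sum(), 2)
        b += [(-10.0, float(np.log(n_tot) + 12.0))] * dm.sizes[3]
        return b

    def _finalize(self, res, spec, dm, packed, histories) -> None:
        beta = res.x
        nll = float(res.fun)
        grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.inf
        self.spec_ = spec
        self.design_ = dm
        self.beta_ = beta
        self.loglik_ = -nll
        self.n_params_ = dm.n_params
        # convergence: optimizer success plus a gradient norm small relative to
        # the NLL magnitude (finite-difference gradients put an absolute 1e-5
        # threshold out of reach on likelihoods of order 1e3)
        self.converged_ = bool(res.success) and grad_norm < 1e-3 * max(1.0, abs(nll))
        self.diagnostics_ = {
            "grad_norm": grad_norm,
            "optimizer_status": res.message,
            "n_iter": int(res.nit),
        }
        self.group_names_ = packed.group_names
        self.occasions_ = list(histories.occasions)
        self.n_observed_ = packed.n_observed.astype(int)
        self._packed = packed
        self._signature = _data_signature(histories)
        phi, p, pent, N = dm.natural_parameters(beta)
        self.phi_, self.p_, self.pent_, self.nhat_ = phi, p, pent, N
        at_bound = np.any(np.abs(beta[: sum(dm.sizes[:3])]) >= 14.999)
        self.boundary_ = bool(at_bound)
        if at_bound:
            warnings.warn("estimate at link-scale boundary (p or phi near 0/1)", stacklevel=3)
        # observed-information covariance on the link scale
        with np.errstate(all="ignore"):
            H = approx_hess(beta, popan_negative_log_likelihood, args=(dm, packed))
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
        if np.any(~np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            cov = np.linalg.pinv(H)
            if np.any(np.diag(cov) < 0):
                warnings.warn("non-positive-definite information; SEs unreliable", stacklevel=3)
                cov = np.where(np.isfinite(cov), cov, 0.0)
        self.cov_ = cov
        # delta-method SE for N = exp(X_n beta_N)
        s = np.cumsum(dm.sizes)
        cov_n = cov[s[2]: s[3], s[2]: s[3]]
        eta_var = np.einsum("ij,jk,ik->i", dm.X_n, cov_n, dm.X_n)
        self.nhat_se_ = self.nhat_ * np.sqrt(np.clip(eta_var, 0.0, None))
        chat = max(self.chat, 1.0) if self.clamp_chat else self.chat
        self.chat_used_ = chat
        n_eff = self.n_eff if self.n_eff is not None else int(packed.n_observed.sum())
        self.n_eff_ = n_eff
        from .selection import qaicc

        self.qaicc_ = qaicc(self.loglik_, self.n_params_, chat, n_eff)

    # -- derived quantities ---------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "beta_"):
            raise RuntimeError("estimator is not fitted")

    def _abundance_path(self, beta: np.ndarray) -> np.ndarray:
        """(G, K) expected daily abundance implied by link-scale beta."""
        phi, p, pent, N = self.design_.natural_parameters(beta)
        G, K = pent.shape
        out = np.empty((G, K))
        B = pent * N[:, None]  # entrants per occasion
        out[:, 0] = B[:, 0]
        for t in range(K - 1):
            out[:, t + 1] = out[:, t] * phi[:, t] + B[:, t + 1]
        return out

    def derived_abundance(self, require_convergence: bool = True) -> pd.DataFrame:
        """Daily abundance N_t per group with delta-method SEs.

        Entrants are B_t = N_hat * pent_t; N_1 = B_1 and
        N_{t+1} = N_t * phi_t + B_{t+1}, so the entrants sum to the
        superpopulation size in each group.
        """
        self._check_fitted()
        if require_convergence and not self.converged_:
            raise FitError(f"fit did not converge: {self.diagnostics_}")
        G, K = len(self.group_names_), self.design_.K
        path = self._abundance_path(self.beta_)
        # numerical jacobian of the (G*K) abundance path wrt beta
        eps = 1e-5
        J = np.empty((G * K, self.beta_.size))
        for j in range(self.beta_.size):
            bp = self.beta_.copy()
            bm = self.beta_.copy()
            bp[j] += eps
            bm[j] -= eps
            J[:, j] = (self._abundance_path(bp) - self._abundance_path(bm)).ravel() / (2 * eps)
        var = np.einsum("ij,jk,ik->i", J, self.cov_, J).reshape(G, K)
        se = np.sqrt(np.clip(var, 0.0, None))
        B = self.pent_ * self.nhat_[:, None]
        rows = []
        for gi, g in enumerate(self.group_names_):
            for k in range(K):
                rows.append(
                    {
                        "group": g,
                        "occasion": k,
                        "date": self.occasions_[k],
                        "abundance": path[gi, k],
                        "se": se[gi, k],
                        "entrants": B[gi, k],
                    }
                )
        return pd.DataFrame(rows)

    def prob_ever_detected(self) -> np.ndarray:
        """Per-group probability that a superpopulation member is seen at all."""
        self._check_fitted()
        return np.array(
            [
                1.0 - prob_never_detected(self.pent_[g], self.phi_[g], self.p_[g])
                for g in range(len(self.group_names_))
            ]
        )


def fit_model(
    spec: str | PopanModelSpec,
    histories,
    effort: np.ndarray | None = None,
    chat: float = 1.0,
    **kwargs,
) -> PopanEstimator:
    """Functional wrapper: fit one model and return the fitted estimator."""
    est = PopanEstimator(formula=spec, chat=chat, **kwargs)
    return est.fit(histories, effort=effort)


def derived_daily_abundance(fit: PopanEstimator) -> pd.DataFrame:
    return fit.derived_abundance()
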