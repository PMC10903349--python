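"""Model-structure grammar for POPAN parameters.

A model is written in the compact notation used throughout the
capture-recapture literature, e.g.::

    Phi(g+T^2) p(g+t) pent(g*T^2) N(g)

Each parameter (apparent survival ``Phi``, detection ``p``, entry
probability ``pent``, superpopulation size ``N``) takes an expression over

- ``.``   constant,
- ``g``   sex/group effect,
- ``t``   factorial (fully time-dependent) effect,
- ``T``   linear trend on the standardized occasion index,
- ``T^2`` quadratic trend (columns T and T^2),

combined additively (``+``: shared time effect, group offset) or
interactively (``*``: group-specific time effects). Detection may carry an
additive sampling-effort covariate, written ``p(g+t+effort)``.

Design-matrix construction uses a logit link for Phi and p, a log link for
N, and a within-group multinomial-logit (softmax) link for pent with the
first occasion as the reference cell. Because softmax is invariant to
adding a constant within a group, intercept and group-offset columns are
not identifiable for pent and are silently dropped (``pent(g+T)`` fits the
same model as ``pent(T)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = ["TermExpr", "PopanModelSpec", "parse_model_formula", "build_design_matrices"]

_TIME_TERMS = ("t", "T", "T^2")
_PARAM_RE = re.compile(
    r"^\s*Phi\s*\((?P<phi>[^)]*)\)\s*"
    r"p\s*\((?P<p>[^)]*)\)\s*"
    r"pent\s*\((?P<pent>[^)]*)\)\s*"
    r"N\s*\((?P<N>[^)]*)\)\s*$",
    re.IGNORECASE,
)


class FormulaError(ValueError):
    """Malformed model formula."""


@dataclass(frozen=True)
class TermExpr:
    """Parsed expression for one POPAN parameter."""

    group: bool = False
    time: str | None = None  # None | 't' | 'T' | 'T^2'
    interactive: bool = False  # group x time interaction
    effort: bool = False

    def label(self) -> str:
        parts: list[str] = []
        if self.group:
            parts.append("g")
        if self.time:
            if self.group and self.interactive:
                body = "*".join(["g", self.time])
                parts = [body]
            else:
                parts.append(self.time)
        out = "+".join(parts) if parts else "."
        if self.effort:
            out = out + "+effort" if out != "." else "effort"
        return out


def _parse_expr(text: str, where: str) -> TermExpr:
    raw = text.replace(" ", "")
    if raw == "":
        raise FormulaError(f"empty expression for {where}")
    # tokenize on + and * keeping operators
    tokens = re.split(r"([+*])", raw)
    group = False
    time: str | None = None
    interactive = False
    effort = False
    prev_op = "+"
    for pos, tok in enumerate(tokens):
        if tok in ("+", "*"):
            prev_op = tok
            continue
        if tok == ".":
            continue
        if tok == "g":
            group = True
            continue
        if tok == "effort":
            effort = True
            continue
        if tok in _TIME_TERMS or tok.upper() == "T^2":
            t = "T^2" if tok.upper() == "T^2" else tok
            if time is not None:
                raise FormulaError(f"{where}: more than one time term (position {pos})")
            time = t
            if prev_op == "*":
                interactive = True
            continue
        raise FormulaError(f"{where}: unknown term {tok!r} (position {pos})")
    if interactive and not group:
        raise FormulaError(f"{where}: interaction '*' requires a group term")
    return TermExpr(group=group, time=time, interactive=interactive, effort=effort)


@dataclass(frozen=True)
class PopanModelSpec:
    """Symbolic structure of one POPAN model."""

    phi: TermExpr
    p: TermExpr
    pent: TermExpr
    n: TermExpr

    def label(self) -> str:
        return (
            f"Phi({self.phi.label()}) p({self.p.label()}) "
            f"pent({self.pent.label()}) N({self.n.label()})"
        )


def parse_model_formula(text: str) -> PopanModelSpec:
    """Parse ``"Phi(...) p(...) pent(...) N(...)"`` into a model spec."""
    m = _PARAM_RE.match(text)
    if not m:
        raise FormulaError(
            f"formula {text!r} does not match 'Phi(expr) p(expr) pent(expr) N(expr)'"
        )
    phi = _parse_expr(m.group("phi"), "Phi")
    p = _parse_expr(m.group("p"), "p")
    pent = _parse_expr(m.group("pent"), "pent")
    n = _parse_expr(m.group("N"), "N")
    if phi.effort or pent.effort or n.effort:
        raise FormulaError("effort covariate is only supported on p")
    if n.time is not None:
        raise FormulaError("N may only be '.' or 'g'")
    return PopanModelSpec(phi, p, pent, n)


def _std(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _time_columns(expr_time: str, z: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Columns for one group's time slots (R rows)."""
    R = z.size
    if expr_time == "t":
        cols = np.zeros((R, R - 1))
        for j in range(1, R):
            cols[j, j - 1] = 1.0
        return cols, [f"t{j + 1}" for j in range(1, R)]
    if expr_time == "T":
        return z[:, None], ["T"]
    if expr_time == "T^2":
        return np.column_stack([z, z**2]), ["T", "T^2"]
    raise AssertionError(expr_time)


def _build_rate_matrix(
    expr: TermExpr,
    n_slots: int,
    groups: Sequence[str],
    z: np.ndarray,
    effort_z: np.ndarray | None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for Phi or p: rows are group-major (group, slot)."""
    G = len(groups)
    rows = G * n_slots
    blocks: list[np.ndarray] = [np.ones((rows, 1))]
    names: list[str] = ["(intercept)"]
    grp_idx = np.repeat(np.arange(G), n_slots)
    if expr.group:
        for gi in range(1, G):
            blocks.append((grp_idx == gi).astype(float)[:, None])
            names.append(f"g[{groups[gi]}]")
    if expr.time:
        tc, tn = _time_columns(expr.time, z)
        shared = np.tile(tc, (G, 1))
        if expr.interactive:
            # group-specific time effects: shared main effect + interactions
            blocks.append(shared)
            names.extend(tn)
            for gi in range(1, G):
                inter = shared * (grp_idx == gi).astype(float)[:, None]
                blocks.append(inter)
                names.extend(f"{n}:g[{groups[gi]}]" for n in tn)
        else:
            blocks.append(shared)
            names.extend(tn)
    if expr.effort:
        if effort_z is None:
            raise ValueError("model requests effort covariate but no effort supplied")
        blocks.append(np.tile(effort_z[:n_slots, None], (G, 1)))
        names.append("effort")
    X = np.column_stack(blocks)
    _check_rank(X, names, expr)
    return X, names


def _build_pent_matrix(
    expr: TermExpr, K: int, groups: Sequence[str], z: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for pent (K rows per group, softmax within group).

    Constant-within-group columns are dropped (non-identifiable under the
    within-group softmax); the first occasion is the reference cell for
    factorial time.
    """
    G = len(groups)
    rows = G * K
    grp_idx = np.repeat(np.arange(G), K)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if expr.time:
        tc, tn = _time_columns(expr.time, z)
        shared = np.tile(tc, (G, 1))
        if expr.interactive:
            for gi in range(G):
                blk = shared * (grp_idx == gi).astype(float)[:, None]
                blocks.append(blk)
                names.extend(f"{n}:g[{groups[gi]}]" for n in tn)
        else:
            blocks.append(shared)
            names.extend(tn)
    if not blocks:  # pent(.) or pent(g): uniform entry within each group
        return np.zeros((rows, 0)), []
    X = np.column_stack(blocks)
    _check_rank(X, names, expr)
    return X, names


def _build_n_matrix(expr: TermExpr, groups: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    G = len(groups)
    X = np.ones((G, 1))
    names = ["(intercept)"]
    if expr.group:
        for gi in range(1, G):
            col = np.zeros(G)
            col[gi] = 1.0
            X = np.column_stack([X, col])
            names.append(f"g[{groups[gi]}]")
    return X, names


def _check_rank(X: np.ndarray, names: list[str], expr: TermExpr) -> None:
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name a maximal independent set; the rest are confounded
        _, _, piv = scipy.linalg.qr(X, pivoting=True)
        bad = [names[j] for j in piv[r:]]
        raise ValueError(
            f"rank-deficient design for expression {expr.label()!r}; "
            f"confounded columns: {bad}"
        )


class DesignMatrices:
    """Bundled design matrices for one model on one dataset."""

    def __init__(
        self,
        spec: PopanModelSpec,
        K: int,
        groups: Sequence[str],
        effort: np.ndarray | None = None,
    ) -> None:
        if K < 2:
            raise ValueError("need at least 2 occasions")
        if spec.phi.time == "t" and K == 2:
            pass  # single interval; factorial == constant
        self.spec = spec
        self.K = K
        self.groups = list(groups)
        z_occ = _std(np.arange(K))
        z_int = _std(np.arange(K - 1))  # interval j spans occasions j..j+1
        effort_z = _std(effort) if effort is not None else None
        if spec.p.effort and effort is None:
            raise ValueError("spec requests effort covariate on p but effort is None")
        self.X_phi, self.names_phi = _build_rate_matrix(spec.phi, K - 1, groups, z_int, None)
        self.X_p, self.names_p = _build_rate_matrix(spec.p, K, groups, z_occ, effort_z)
        self.X_pent, self.names_pent = _build_pent_matrix(spec.pent, K, groups, z_occ)
        self.X_n, self.names_n = _build_n_matrix(spec.n, groups)
        self.sizes = tuple(
            X.shape[1] for X in (self.X_phi, self.X_p, self.X_pent, self.X_n)
        )
        self.n_params = sum(self.sizes)

    def split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        beta = np.asarray(beta, dtype=float)
        if beta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {beta.size}")
        s = np.cumsum(self.sizes)[:-1]
        return tuple(np.split(beta, s))  # type: ignore[return-value]

    def natural_parameters(
        self, beta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Map link-scale beta to (phi[G,K-1], p[G,K], pent[G,K], N[G])."""
        from scipy.special import expit, softmax

        b_phi, b_p, b_pent, b_n = self.split(beta)
        G, K = len(self.groups), self.K
        phi = expit(self.X_phi @ b_phi).reshape(G, K - 1)
        p = expit(self.X_p @ b_p).reshape(G, K)
        eta = (self.X_pent @ b_pent).reshape(G, K) if b_pent.size else np.zeros((G, K))
        pent = softmax(eta, axis=1)
        N = np.exp(self.X_n @ b_n)
        return phi, p, pent, N


def build_design_matrices(
    spec: PopanModelSpec,
    K: int,
    groups: Sequence[str],
    effort: np.ndarray | None = None,
) -> DesignMatrices:
    return DesignMatrices(spec, K, groups, effort)
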