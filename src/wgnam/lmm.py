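"""REML estimation of the NAM linear mixed model.

The model for the N plot observations is

    y = X tau + Z0 u0 + Zg u_g + eps,   eps ~ N(0, sigma2_e I)

with u_g the n_g line-level genetic effects.  Genetic structure is expressed
through line-space covariance kernels: a polygenic identity term, a common
whole-genome marker kernel K = c * sum_j Q_j Q_j' built from founder
probabilities, and one rank-n_f term Q_j Q_j' per selected QTL, each with its
own variance component.  All computation is reduced to n_g-dimensional
symmetric factorizations: with variance ratios gamma_k = sigma2_k / sigma2_e
and Gamma = sum_k gamma_k C_k,

    V = sigma2_e H,   H = I_N + Zg Gamma Zg',
    H^-1 = I - Zg (Gamma^-1 + Zg'Zg)^-1 Zg'

evaluated via A = I + M^(1/2) Gamma M^(1/2) (M = Zg'Zg) so that ratios may
sit exactly on the zero boundary.  sigma2_e is profiled out; the profiled
residual log-likelihood is maximized by L-BFGS-B with analytic gradients,
components constrained to be non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.linalg import LinAlgError
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.stats import chi2

from .probs import FounderProbabilities
from .types import DataError

GAMMA_UPPER = 1e6
#: ratios below this are reported as an exact zero component
ZERO_TOL = 1e-8
P_FLOOR = 1e-300


class FitError(RuntimeError):
    """Raised when a REML fit cannot be performed."""


# ------------------------------------------------------------------ terms

@dataclass
class RandomTerm:
    """One genetic variance structure in line space.

    ``kernel`` is a dense (n_g, n_g) PSD matrix; ``factor`` a low-rank
    (n_g, k) factor with kernel = factor @ factor.T.  With both ``None`` the
    term is the iid polygenic identity.
    """

    name: str
    kernel: np.ndarray | None = None
    factor: np.ndarray | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def matrix(self, n_g: int) -> np.ndarray:
        if self.kernel is not None:
            return self.kernel
        if self.factor is not None:
            return self.factor @ self.factor.T
        return np.eye(n_g)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of a dense kernel (values, vectors)."""
        if self._eig is None:
            if self.kernel is None:
                raise FitError("eigendecomposition requested for non-dense term")
            vals, vecs = eigh(self.kernel)
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig


@dataclass(frozen=True)
class GroupTerm:
    """An iid non-genetic random block (e.g. replicate), given by integer
    group codes per observation."""

    name: str
    codes: np.ndarray  # (N,) int in [0, n_levels)

    @property
    def n_levels(self) -> int:
        return int(self.codes.max()) + 1


@dataclass
class MixedModelSpec:
    """Data and structure of one mixed-model fit.

    ``line_index`` maps each observation to a line (row of the kernels), with
    -1 for observations (checks) that carry no genetic effect.
    """

    y: np.ndarray
    X: np.ndarray
    line_index: np.ndarray
    n_lines: int
    terms: list[RandomTerm]
    group_terms: list[GroupTerm] = field(default_factory=list)
    fixed_names: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.line_index = np.asarray(self.line_index, dtype=int)
        N = self.y.shape[0]
        if self.X.shape[0] != N or self.line_index.shape[0] != N:
            raise DataError("y, X and line_index must have equal length")
        if np.any(self.line_index >= self.n_lines):
            raise DataError("line_index out of range")
        if self.fixed_names is None:
            self.fixed_names = [f"beta{k}" for k in range(self.X.shape[1])]


@dataclass(frozen=True)
class VarianceComponents:
    residual: float
    components: dict[str, float]

    def __post_init__(self):
        if self.residual < 0 or any(v < 0 for v in self.components.values()):
            raise DataError("variance components must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.components[name] if name != "residual" else self.residual


@dataclass
class MixedModelFit:
    """REML solution: variance components, log-likelihood, fixed effects and
    the projector caches used for BLUPs and the genome scan."""

    spec: MixedModelSpec
    varcomps: VarianceComponents
    loglik: float
    beta: np.ndarray
    converged: bool
    n_iter: int
    message: str
    # caches (line space): q_H = Zg' P_H y, T_H = Zg' P_H Zg, with
    # P_V = P_H / sigma2_e for the V-scale projector.
    _q_H: np.ndarray | None = field(default=None, repr=False)
    _T_H_fn: object = field(default=None, repr=False)
    _T_H: np.ndarray | None = field(default=None, repr=False)
    _gamma: dict[str, float] = field(default_factory=dict, repr=False)

    @property
    def sigma2_e(self) -> float:
        return self.varcomps.residual

    @property
    def q_V(self) -> np.ndarray:
        """Zg' P y on the V scale (n_g vector)."""
        return self._q_H / self.sigma2_e

    @property
    def T_V(self) -> np.ndarray:
        """Zg' P Zg on the V scale (n_g x n_g), computed lazily."""
        if self._T_H is None:
            self._T_H = self._T_H_fn()
        return self._T_H / self.sigma2_e

    def blup_lines(self, term: str | None = None) -> np.ndarray:
        """Line-level BLUPs: total genetic (default) or a single term."""
        n_g = self.spec.n_lines
        if term is None:
            out = np.zeros(n_g)
            for t in self.spec.terms:
                out += self.blup_lines(t.name)
            return out
        for t in self.spec.terms:
            if t.name == term:
                g = self._gamma[t.name]
                if g == 0.0:
                    return np.zeros(n_g)
                if t.factor is not None:
                    return g * (t.factor @ (t.factor.T @ self._q_H))
                if t.kernel is not None:
                    return g * (t.kernel @ self._q_H)
                return g * self._q_H
        raise KeyError(term)


@dataclass(frozen=True)
class MarkerBlup:
    """Founder-effect BLUPs at one marker: effects, their variance, and the
    prediction error variance (PEV), with Var(a~) + PEV = sigma2 * I."""

    marker_id: str
    effects: np.ndarray          # (n_f,)
    blup_variance: np.ndarray    # (n_f, n_f)
    pev: np.ndarray              # (n_f, n_f)
    sigma2: float                # prior per-effect variance


# ------------------------------------------------------------------ kernel

def build_marker_kernel(probs: FounderProbabilities,
                        exclude: set[str] | frozenset[str] = frozenset(),
                        ) -> tuple[np.ndarray, float]:
    """Whole-genome founder-probability kernel K = c * sum_{j not excluded}
    Q_j Q_j', with c = n_g / trace(sum Q_j Q_j') for conditioning.

    The constant c is returned so BLUPs can be back-transformed to the
    original probability scale.
    """
    keep = [j for j, m in enumerate(probs.marker_ids) if m not in exclude]
    if not keep:
        raise DataError("kernel requested over an empty marker set")
    Q = probs.p[:, keep, :].reshape(probs.n_lines, -1)
    K0 = Q @ Q.T
    tr = float(np.trace(K0))
    if tr <= 0:
        raise DataError("kernel trace is zero")
    c = probs.n_lines / tr
    return c * K0, c


# ------------------------------------------------------------------ engine

def _drop_rank_deficient(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Remove trailing confounded fixed-effect columns (QR with pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return X, names
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = sorted(piv[:rank])
        dropped = [names[k] for k in sorted(piv[rank:])]
        warnings.warn(f"dropping confounded fixed-effect columns: {dropped}")
        return X[:, keep], [names[k] for k in keep]
    return X, names


class _Workspace:
    """Precomputed sufficient statistics shared by all likelihood
    evaluations of one fit."""

    def __init__(self, spec: MixedModelSpec):
        y, X = spec.y, spec.X
        ok = np.isfinite(y)
        if not ok.all():
            raise DataError("y contains non-finite values; drop them first")
        self.N = y.shape[0]
        self.X, self.fixed_names = _drop_rank_deficient(X, list(spec.fixed_names))
        self.p = self.X.shape[1]
        if self.N <= self.p:
            raise FitError("more fixed-effect columns than observations")
        self.n_g = spec.n_lines
        li = spec.line_index
        self.has_groups = bool(spec.group_terms)

        # line-block statistics
        linked = li >= 0
        self.m = np.bincount(li[linked], minlength=self.n_g).astype(float)
        Zty = np.zeros(self.n_g)
        np.add.at(Zty, li[linked], y[linked])
        ZtX = np.zeros((self.n_g, self.p))
        np.add.at(ZtX, li[linked], self.X[linked])
        self.Zty, self.ZtX = Zty, ZtX
        self.yty = float(y @ y)
        self.Xty = self.X.T @ y
        self.XtX = self.X.T @ self.X
        self.y = y
        self.li = li
        self.spec = spec

        if self.has_groups:
            cols = [self._incidence(li, self.n_g, linked)]
            self.block_slices = [slice(0, self.n_g)]
            start = self.n_g
            for gt in spec.group_terms:
                cols.append(self._incidence(gt.codes, gt.n_levels,
                                            np.ones(self.N, dtype=bool)))
                self.block_slices.append(slice(start, start + gt.n_levels))
                start += gt.n_levels
            W = np.hstack(cols)
            self.q_dim = start
            self.WtW = W.T @ W
            self.WtX = W.T @ self.X
            self.Wty = W.T @ y
        else:
            self.q_dim = self.n_g

    @staticmethod
    def _incidence(codes: np.ndarray, n: int, mask: np.ndarray) -> np.ndarray:
        Z = np.zeros((codes.shape[0], n))
        idx = np.flatnonzero(mask)
        Z[idx, codes[idx]] = 1.0
        return Z


def _gamma_matrix(terms: Sequence[RandomTerm], gammas: np.ndarray, n_g: int) -> np.ndarray:
    G = np.zeros((n_g, n_g))
    for t, g in zip(terms, gammas):
        if g == 0.0:
            continue
        if t.kernel is not None:
            G += g * t.kernel
        elif t.factor is not None:
            G += g * (t.factor @ t.factor.T)
        else:
            G[np.diag_indices(n_g)] += g
    return G


class _SymPath:
    """General no-group-terms evaluator via A = I + M^1/2 Gamma M^1/2.

    All H^-1 quadratic forms are written as (within-line part) +
    u' A^-1 u with u = M^-1/2 Zg'(.), which stays cancellation-free even
    when variance ratios are enormous (near-noiseless data):

        Zg'H^-1 Zg = M^1/2 A^-1 M^1/2
        X'H^-1 X   = (XtX - u_X'u_X) + u_X'A^-1 u_X
    """

    def __init__(self, ws: _Workspace, terms: Sequence[RandomTerm]):
        self.ws = ws
        self.terms = terms
        self.ms = np.sqrt(ws.m)
        inv = np.zeros_like(self.ms)
        nz = self.ms > 0
        inv[nz] = 1.0 / self.ms[nz]
        self.u_X = inv[:, None] * ws.ZtX       # M^-1/2 Zg'X
        self.u_y = inv * ws.Zty                # M^-1/2 Zg'y
        # within-line (line-space-orthogonal) parts; structurally >= 0
        self.wXX = ws.XtX - self.u_X.T @ self.u_X
        self.wXy = ws.Xty - self.u_X.T @ self.u_y
        self.wyy = ws.yty - float(self.u_y @ self.u_y)

    def _factor(self, gammas: np.ndarray):
        ws = self.ws
        G = _gamma_matrix(self.terms, gammas, ws.n_g)
        A = G * np.outer(self.ms, self.ms)
        A[np.diag_indices(ws.n_g)] += 1.0
        cA = cho_factor(A, lower=True)
        logdetH = 2.0 * float(np.log(np.diag(cA[0])).sum())
        return cA, logdetH

    def value(self, gammas: np.ndarray):
        ws = self.ws
        cA, logdetH = self._factor(gammas)
        Au_y = cho_solve(cA, self.u_y)
        Au_X = cho_solve(cA, self.u_X)
        yHy = self.wyy + float(self.u_y @ Au_y)
        XHy = self.wXy + self.u_X.T @ Au_y
        XHX = self.wXX + self.u_X.T @ Au_X
        try:
            cC = cho_factor(XHX)
        except LinAlgError as e:
            raise FitError(f"singular fixed-effect system: {e}")
        beta = cho_solve(cC, XHy)
        yPy = yHy - float(XHy @ beta)
        if yPy <= 0:
            raise FitError("non-positive residual quadratic form")
        logdetC = 2.0 * float(np.log(np.abs(np.diag(cC[0]))).sum())
        return {"cA": cA, "Au_y": Au_y, "Au_X": Au_X, "XHy": XHy, "cC": cC,
                "beta": beta, "yPy": yPy, "logdetH": logdetH,
                "logdetC": logdetC}

    def loglik(self, core) -> float:
        ws = self.ws
        df = ws.N - ws.p
        s2 = core["yPy"] / df
        return -0.5 * (df * (np.log(2 * np.pi * s2) + 1.0)
                       + core["logdetH"] + core["logdetC"])

    def _zq(self, core) -> np.ndarray:
        """q = Zg' P_H y (plus Zg'H^-1 X for reuse)."""
        ZHy = self.ms * core["Au_y"]
        ZHX = self.ms[:, None] * core["Au_X"]
        return ZHy - ZHX @ core["beta"], ZHX

    def T_H(self, core) -> np.ndarray:
        ws = self.ws
        Ainv = cho_solve(core["cA"], np.eye(ws.n_g))
        ZHZ = np.outer(self.ms, self.ms) * Ainv
        _, ZHX = self._zq(core)
        return ZHZ - ZHX @ cho_solve(core["cC"], ZHX.T)

    def gradient(self, gammas: np.ndarray, core) -> np.ndarray:
        ws = self.ws
        df = ws.N - ws.p
        T = self.T_H(core)
        q, _ = self._zq(core)
        grad = np.empty(len(self.terms))
        for k, t in enumerate(self.terms):
            if t.kernel is not None:
                tr = float(np.sum(t.kernel * T))
                quad = float(q @ t.kernel @ q)
            elif t.factor is not None:
                TF = T @ t.factor
                tr = float(np.sum(t.factor * TF))
                qf = t.factor.T @ q
                quad = float(qf @ qf)
            else:
                tr = float(np.trace(T))
                quad = float(q @ q)
            grad[k] = -0.5 * (tr - df * quad / core["yPy"])
        return grad


class _SpectralPath(_SymPath):
    """Fast path when m is uniform and the terms are a subset of
    {identity, one dense kernel}: everything is diagonal in the kernel
    eigenbasis and each evaluation is O(n_g p^2)."""

    def __init__(self, ws: _Workspace, terms: Sequence[RandomTerm]):
        self.ws = ws
        self.terms = terms
        self.r = float(ws.m[0])
        dense = [t for t in terms if t.kernel is not None]
        if dense:
            lam, U = dense[0].eig()
            self.lam, self.U = lam, U
            self.Zty_t = U.T @ ws.Zty
            self.ZtX_t = U.T @ ws.ZtX
        else:
            self.lam, self.U = np.zeros(ws.n_g), None
            self.Zty_t, self.ZtX_t = ws.Zty, ws.ZtX
        # spectra per term aligned with self.terms
        self.spectra = []
        for t in terms:
            self.spectra.append(self.lam if t.kernel is not None
                                else np.ones(ws.n_g))
        # within-line parts (cancellation-free split, as in _SymPath)
        self.wXX = ws.XtX - ws.ZtX.T @ ws.ZtX / self.r
        self.wXy = ws.Xty - ws.ZtX.T @ ws.Zty / self.r
        self.wyy = ws.yty - float(ws.Zty @ ws.Zty) / self.r

    def value(self, gammas: np.ndarray):
        ws = self.ws
        gtil = np.zeros(ws.n_g)
        for s, g in zip(self.spectra, gammas):
            gtil = gtil + g * s
        a = 1.0 + self.r * gtil
        logdetH = float(np.log(a).sum())
        ia_r = 1.0 / (a * self.r)  # diag of M^-1/2 A^-1 M^-1/2
        yHy = self.wyy + float(self.Zty_t @ (ia_r * self.Zty_t))
        XHy = self.wXy + self.ZtX_t.T @ (ia_r * self.Zty_t)
        XHX = self.wXX + self.ZtX_t.T @ (ia_r[:, None] * self.ZtX_t)
        try:
            cC = cho_factor(XHX)
        except LinAlgError as e:
            raise FitError(f"singular fixed-effect system: {e}")
        beta = cho_solve(cC, XHy)
        yPy = yHy - float(XHy @ beta)
        if yPy <= 0:
            raise FitError("non-positive residual quadratic form")
        logdetC = 2.0 * float(np.log(np.abs(np.diag(cC[0]))).sum())
        return {"a": a, "cC": cC, "beta": beta, "yPy": yPy,
                "logdetH": logdetH, "logdetC": logdetC}

    def _zq_t(self, core):
        V = self.ZtX_t / core["a"][:, None]      # Zg'H^-1 X in eigenbasis
        q = self.Zty_t / core["a"] - V @ core["beta"]
        return q, V

    def gradient(self, gammas: np.ndarray, core) -> np.ndarray:
        ws = self.ws
        df = ws.N - ws.p
        q, V = self._zq_t(core)
        VC = cho_solve(core["cC"], V.T)          # (p, n_g)
        diag_corr = np.einsum("ij,ji->i", V, VC)
        T_diag = self.r / core["a"] - diag_corr
        grad = np.empty(len(self.terms))
        for k, s in enumerate(self.spectra):
            tr = float(s @ T_diag)
            # off-diagonal contributions vanish against a diagonal spectrum
            quad = float(q @ (s * q))
            grad[k] = -0.5 * (tr - df * quad / core["yPy"])
        return grad

    def _zq(self, core):
        q_t, V_t = self._zq_t(core)
        if self.U is None:
            return q_t, V_t
        return self.U @ q_t, self.U @ V_t

    def T_H(self, core) -> np.ndarray:
        _, V_t = self._zq_t(core)
        Tt = np.diag(self.r / core["a"]) - V_t @ cho_solve(core["cC"], V_t.T)
        if self.U is None:
            return Tt
        return self.U @ Tt @ self.U.T


class _GenericPath(_SymPath):
    """Path with non-genetic group blocks: inverts the full block-diagonal
    Gamma, so ratios are kept a hair above zero."""

    LB = 1e-10

    def __init__(self, ws: _Workspace, terms: Sequence[RandomTerm]):
        self.ws = ws
        self.terms = terms
        self.n_group = len(ws.spec.group_terms)

    def _gamma_full(self, gammas: np.ndarray) -> np.ndarray:
        ws = self.ws
        G = np.zeros((ws.q_dim, ws.q_dim))
        gl = ws.block_slices[0]
        G[gl, gl] = _gamma_matrix(self.terms, np.maximum(gammas[:len(self.terms)],
                                                         self.LB), ws.n_g)
        for b, sl in enumerate(ws.block_slices[1:]):
            g = max(gammas[len(self.terms) + b], self.LB)
            G[sl, sl] = g * np.eye(sl.stop - sl.start)
        return G

    def value(self, gammas: np.ndarray):
        ws = self.ws
        G = self._gamma_full(gammas)
        cG = cho_factor(G, lower=True)
        B = cho_solve(cG, np.eye(ws.q_dim)) + ws.WtW
        cB = cho_factor(B, lower=True)
        logdetH = 2.0 * float(np.log(np.diag(cG[0])).sum()) \
            + 2.0 * float(np.log(np.diag(cB[0])).sum())
        bWty = cho_solve(cB, ws.Wty)
        bWtX = cho_solve(cB, ws.WtX)
        yHy = ws.yty - float(ws.Wty @ bWty)
        XHy = ws.Xty - ws.WtX.T @ bWty
        XHX = ws.XtX - ws.WtX.T @ bWtX
        cC = cho_factor(XHX)
        beta = cho_solve(cC, XHy)
        yPy = yHy - float(XHy @ beta)
        if yPy <= 0:
            raise FitError("non-positive residual quadratic form")
        logdetC = 2.0 * float(np.log(np.abs(np.diag(cC[0]))).sum())
        return {"cB": cB, "bWty": bWty, "bWtX": bWtX, "XHy": XHy, "cC": cC,
                "beta": beta, "yPy": yPy, "logdetH": logdetH, "logdetC": logdetC}

    def _wq(self, core):
        ws = self.ws
        WHy = ws.Wty - ws.WtW @ core["bWty"]
        WHX = ws.WtX - ws.WtW @ core["bWtX"]
        return WHy - WHX @ core["beta"], WHX

    def _T_full(self, core) -> np.ndarray:
        ws = self.ws
        Binv = cho_solve(core["cB"], np.eye(ws.q_dim))
        WHW = ws.WtW - ws.WtW @ Binv @ ws.WtW
        _, WHX = self._wq(core)
        return WHW - WHX @ cho_solve(core["cC"], WHX.T)

    def T_H(self, core) -> np.ndarray:
        gl = self.ws.block_slices[0]
        return self._T_full(core)[gl, gl]

    def _zq(self, core):
        q, WHX = self._wq(core)
        gl = self.ws.block_slices[0]
        return q[gl], WHX[gl]

    def gradient(self, gammas: np.ndarray, core) -> np.ndarray:
        ws = self.ws
        df = ws.N - ws.p
        T = self._T_full(core)
        q, _ = self._wq(core)
        grad = np.empty(len(gammas))
        gl = ws.block_slices[0]
        Tg, qg = T[gl, gl], q[gl]
        for k, t in enumerate(self.terms):
            C = t.matrix(ws.n_g)
            grad[k] = -0.5 * (float(np.sum(C * Tg))
                              - df * float(qg @ C @ qg) / core["yPy"])
        for b, sl in enumerate(ws.block_slices[1:]):
            grad[len(self.terms) + b] = -0.5 * (
                float(np.trace(T[sl, sl]))
                - df * float(q[sl] @ q[sl]) / core["yPy"])
        return grad


def _ols_fit(spec: MixedModelSpec, ws: _Workspace) -> MixedModelFit:
    """No random terms: closed-form residual likelihood."""
    X, y = ws.X, ws.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = ws.N - ws.p
    s2 = float(resid @ resid) / df
    sign, logdetC = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (df * (np.log(2 * np.pi * s2) + 1.0) + logdetC)
    fit = MixedModelFit(spec=spec, varcomps=VarianceComponents(s2, {}),
                        loglik=ll, beta=beta, converged=True, n_iter=0,
                        message="closed form")
    fit._q_H = np.zeros(ws.n_g)
    fit._T_H_fn = lambda: np.zeros((ws.n_g, ws.n_g))
    fit._gamma = {}
    return fit


def fit_reml(spec: MixedModelSpec,
             start: VarianceComponents | dict[str, float] | None = None,
             loglik_tol: float = 1e-6,
             max_iter: int = 100) -> MixedModelFit:
    """Maximize the residual log-likelihood over the variance components.

    ``start`` may give warm-start variances keyed by term name (plus
    'residual'); components are constrained non-negative and boundary
    solutions are reported as exact zeros.
    """
    ws = _Workspace(spec)
    names = [t.name for t in spec.terms] + [g.name for g in spec.group_terms]
    if len(set(names)) != len(names):
        raise DataError("random-term names must be unique")
    if not names:
        return _ols_fit(spec, ws)

    if ws.has_groups:
        path = _GenericPath(ws, spec.terms)
        lb = _GenericPath.LB
    else:
        uniform = ws.m.size > 0 and np.all(ws.m == ws.m[0]) and ws.m[0] > 0
        n_dense = sum(t.kernel is not None for t in spec.terms)
        n_lowrank = sum(t.factor is not None for t in spec.terms)
        if uniform and n_dense <= 1 and n_lowrank == 0:
            path = _SpectralPath(ws, spec.terms)
        else:
            path = _SymPath(ws, spec.terms)
        lb = 0.0

    x0 = np.full(len(names), 0.1)
    if start is not None:
        comp = start.components if isinstance(start, VarianceComponents) else dict(start)
        s2e = comp.get("residual", None)
        if isinstance(start, VarianceComponents):
            s2e = start.residual
        s2e = s2e if s2e and s2e > 0 else float(np.var(ws.y)) or 1.0
        for k, name in enumerate(names):
            if name in comp:
                x0[k] = max(comp[name] / s2e, lb if lb else 1e-6)
    x0 = np.clip(x0, max(lb, 1e-10), GAMMA_UPPER)

    cache: dict = {}

    def fun(g: np.ndarray) -> float:
        key = g.tobytes()
        if cache.get("key") != key:
            cache["key"] = key
            cache["core"] = path.value(g)
            cache["grad"] = None
        return -path.loglik(cache["core"])

    def jac(g: np.ndarray) -> np.ndarray:
        fun(g)
        if cache["grad"] is None:
            cache["grad"] = -path.gradient(g, cache["core"])
        return cache["grad"]

    bounds = [(lb, GAMMA_UPPER)] * len(names)
    opts = {"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-7}

    def _optimize(x_init):
        r = optimize.minimize(fun, x_init, jac=jac, method="L-BFGS-B",
                              bounds=bounds, options=opts)
        if not r.success:
            # line searches can stall at machine precision very close to
            # the optimum; restart once from the current point
            r2 = optimize.minimize(fun, r.x, jac=jac, method="L-BFGS-B",
                                   bounds=bounds, options=opts)
            if r2.fun <= r.fun:
                r2.nit += r.nit
                r = r2
        return r

    res = _optimize(x0)
    if start is not None and np.any(x0 >= 1e4):
        # the profiled surface is nearly flat around warm starts with extreme
        # variance ratios (vanishing residual variance); cross-check against
        # the default start and keep the better optimum
        res_alt = _optimize(np.full(len(names), 0.1))
        if res_alt.fun < res.fun:
            res = res_alt
    # projected gradient: a component pinned at its lower bound with an
    # ascent direction pointing outside the feasible set is at its optimum
    pg = jac(np.asarray(res.x))
    at_lb = np.asarray(res.x) <= lb + 1e-12
    pg = np.where(at_lb & (pg > 0), 0.0, pg)
    grad_ok = float(np.max(np.abs(pg))) < 1e-3 if pg.size else True

    gam = np.asarray(res.x, dtype=float)
    gam[gam < ZERO_TOL] = 0.0
    if not ws.has_groups:
        core = path.value(gam)
    else:
        core = path.value(np.maximum(gam, _GenericPath.LB))
    ll = path.loglik(core)
    df = ws.N - ws.p
    s2e = core["yPy"] / df
    comps = {name: float(g * s2e) for name, g in zip(names, gam)}
    fit = MixedModelFit(
        spec=spec,
        varcomps=VarianceComponents(float(s2e), comps),
        loglik=float(ll),
        beta=core["beta"],
        converged=bool(res.success) or grad_ok,
        n_iter=int(res.nit),
        message=str(res.message))
    fit._q_H, _ = path._zq(core)
    fit._T_H_fn = lambda: path.T_H(core)
    fit._gamma = dict(zip([t.name for t in spec.terms], gam[: len(spec.terms)]))
    if not fit.converged and res.status != 1:
        warnings.warn(f"REML did not converge: {res.message}")
    return fit


# ------------------------------------------------------------------ BLUPs

def blup_marker_effects(fit: MixedModelFit,
                        probs: FounderProbabilities,
                        marker_id: str,
                        which_variance: str,
                        kernel_scale: float | None = None,
                        term_name: str | None = None) -> MarkerBlup:
    """Founder-effect BLUPs, their variance and the PEV at one marker.

    ``which_variance`` chooses the prior: 'common' uses the whole-genome
    component (per-effect variance c * sigma2_K, requiring ``kernel_scale``
    = c); 'selected' uses the marker's own component (term ``term_name`` or
    the marker id).
    """
    j = probs.marker_ids.index(marker_id)
    Qj = probs.marker_slab(j)
    if which_variance == "common":
        if kernel_scale is None:
            raise DataError("kernel_scale (c) is required for the common term")
        name = term_name or "kernel"
        sigma2 = kernel_scale * fit.varcomps.components[name]
    elif which_variance == "selected":
        name = term_name or marker_id
        sigma2 = fit.varcomps.components[name]
    else:
        raise DataError("which_variance must be 'common' or 'selected'")

    n_f = probs.n_founders
    if sigma2 == 0.0:
        z = np.zeros((n_f, n_f))
        return MarkerBlup(marker_id, np.zeros(n_f), z, z.copy(), 0.0)
    effects = sigma2 * (Qj.T @ fit.q_V)
    TQ = fit.T_V @ Qj
    blup_var = sigma2**2 * (Qj.T @ TQ)
    pev = sigma2 * np.eye(n_f) - blup_var
    return MarkerBlup(marker_id, effects, blup_var, pev, sigma2)


# ------------------------------------------------------------------ LRT

def lrt_variance_component(fit_reduced: MixedModelFit,
                           fit_complete: MixedModelFit) -> tuple[float, float]:
    """Likelihood-ratio test of one extra variance component on its boundary.

    The null distribution is the mixture 0.5 chi2_0 + 0.5 chi2_1, so
    p = 0.5 * P(chi2_1 >= Lambda), with p = 1 at Lambda = 0.
    """
    for f in (fit_reduced, fit_complete):
        if not f.converged:
            raise FitError("LRT requested on a non-converged fit")
    lam = max(0.0, 2.0 * (fit_complete.loglik - fit_reduced.loglik))
    if lam == 0.0:
        return 0.0, 1.0
    p = 0.5 * float(chi2.sf(lam, df=1))
    return lam, max(p, P_FLOOR)


def mixture_chi2_pvalue(lam: float) -> float:
    """p-value of the 0.5 chi2_0 + 0.5 chi2_1 mixture for a statistic >= 0."""
    if lam < 0:
        raise DataError("likelihood-ratio statistic must be non-negative")
    if lam == 0.0:
        return 1.0
    return max(0.5 * float(chi2.sf(lam, df=1)), P_FLOOR)
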