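"""Restricted-maximum-likelihood fitting of nested random-intercept models.

The model is

    y = X beta + sum_l Z_l u_l + e,   u_l ~ N(0, sigma_l^2 I),  e ~ N(0, sigma^2 I)

with Z_l the one-hot membership matrix of grouping level l (cell, field,
lymph node, mouse, date).  Writing lambda_l = sigma_l^2 / sigma^2 and
V0 = I + Z Lambda Z', the REML criterion profiled over beta and sigma^2 is

    (n - p) log(sigmahat^2) + log|V0| + log|X' V0^-1 X|,
    sigmahat^2 = r' V0^-1 r / (n - p).

All linear algebra is done in the q-dimensional random-effect space through
the Woodbury identity, so the per-iteration cost is independent of n.  The
variance ratios are optimised by L-BFGS-B on [0, inf) followed by coordinate
Brent polish, which lands boundary solutions exactly at zero and reaches the
closed-form answers of balanced designs to high precision.

Denominator degrees of freedom for single-contrast Wald t tests use the
Satterthwaite approximation: df = 2 f^2 / (g' A g) with f = c' Cov(beta) c,
g its gradient in the variance parameters, and A the asymptotic covariance of
the variance parameters from the (finite-difference) REML Hessian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

__all__ = ["NestedLMM", "LMMFit", "ConvergenceError"]

_LAMBDA_MAX = 1e8


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class LMMFit:
    """Result of a NestedLMM REML fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float                      # residual variance
    variance_components: dict          # level name -> sigma_l^2
    lam: np.ndarray                    # variance ratios sigma_l^2 / sigma^2
    boundary: dict                     # level name -> True if estimate hit 0
    neg2_reml: float
    n_obs: int
    n_params: int
    converged: bool = True
    trace: list = field(default_factory=list)

    @property
    def df_residual(self) -> int:
        return self.n_obs - self.n_params


class NestedLMM:
    """REML fitter for a linear mixed model with independent random intercepts.

    Parameters
    ----------
    X : (n, p) fixed-effects design matrix (full column rank).
    groups : list of (name, codes) pairs; ``codes`` is an integer array of
        group indices (0..q_l-1) per observation, one entry per random level.
    y : (n,) response.
    """

    def __init__(self, X: np.ndarray, groups: list, y: np.ndarray):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        if n <= p:
            raise ValueError("more parameters than observations")
        self.n, self.p = n, p
        self.names = [name for name, _ in groups]
        self.d = len(groups)
        sizes = []
        blocks = []
        for _, codes in groups:
            codes = np.asarray(codes)
            q_l = int(codes.max()) + 1
            Z_l = sp.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, q_l)
            )
            blocks.append(Z_l)
            sizes.append(q_l)
        self.sizes = np.array(sizes, int)
        self.slices = []
        off = 0
        for s in sizes:
            self.slices.append(slice(off, off + s))
            off += s
        self.q = off
        Z = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((n, 0))

        # sufficient cross-products; everything downstream is q- or p-dim
        self.ZtZ = np.asarray((Z.T @ Z).todense()) if self.q else np.zeros((0, 0))
        self.ZtX = Z.T @ X if self.q else np.zeros((0, p))
        self.Zty = Z.T @ y if self.q else np.zeros(0)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # -- per-lambda linear algebra ------------------------------------------

    def _expand(self, lam: np.ndarray) -> np.ndarray:
        s = np.empty(self.q)
        for l, sl in enumerate(self.slices):
            s[sl] = np.sqrt(max(lam[l], 0.0))
        return s

    def _solve(self, lam: np.ndarray):
        """Core quantities at the given variance ratios."""
        s = self._expand(np.asarray(lam, float))
        M = np.eye(self.q) + (s[:, None] * self.ZtZ) * s[None, :]
        L = cho_factor(M, lower=True)
        WtX = s[:, None] * self.ZtX
        Wty = s * self.Zty
        MiWtX = cho_solve(L, WtX)
        MiWty = cho_solve(L, Wty)
        A = self.XtX - WtX.T @ MiWtX          # X' V0^-1 X
        bvec = self.Xty - WtX.T @ MiWty       # X' V0^-1 y
        yv0y = self.yty - Wty @ MiWty         # y' V0^-1 y
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("X' V0^-1 X not positive definite")
        beta = np.linalg.solve(A, bvec)
        quad = max(yv0y - bvec @ beta, 1e-300)
        logdetV0 = 2.0 * np.log(np.diag(L[0])).sum()
        return beta, A, quad, logdetV0, logdetA

    def profiled_neg2reml(self, lam: np.ndarray) -> float:
        n, p = self.n, self.p
        try:
            _, _, quad, logdetV0, logdetA = self._solve(lam)
        except np.linalg.LinAlgError:
            return np.inf
        sigma2 = quad / (n - p)
        return (n - p) * np.log(sigma2) + logdetV0 + logdetA

    def neg2reml_full(self, theta: np.ndarray) -> float:
        """Unprofiled -2 REML log-likelihood (up to constant) in
        theta = (sigma_1^2, ..., sigma_d^2, sigma^2)."""
        theta = np.asarray(theta, float)
        sigma2 = theta[-1]
        if sigma2 <= 0 or np.any(theta[:-1] < 0):
            return np.inf
        lam = theta[:-1] / sigma2
        try:
            _, _, quad, logdetV0, logdetA = self._solve(lam)
        except np.linalg.LinAlgError:
            return np.inf
        return (self.n - self.p) * np.log(sigma2) + logdetV0 + logdetA + quad / sigma2

    # -- fitting -------------------------------------------------------------

    def fit(self, lam0: np.ndarray | None = None, maxiter: int = 200) -> LMMFit:
        n, p, d = self.n, self.p, self.d
        trace: list = []

        def objective(lam):
            val = self.profiled_neg2reml(lam)
            trace.append((np.array(lam, float), float(val)))
            return val

        if d == 0:
            lam = np.zeros(0)
        else:
            x0 = np.full(d, 1.0) if lam0 is None else np.asarray(lam0, float)
            res = minimize(
                objective, x0, method="L-BFGS-B",
                bounds=[(0.0, _LAMBDA_MAX)] * d,
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
            )
            lam = np.clip(res.x, 0.0, _LAMBDA_MAX)
            # coordinate Brent polish: precise boundary/interior optima
            for _ in range(3):
                for l in range(d):
                    def f1(v, l=l):
                        trial = lam.copy()
                        trial[l] = v
                        return objective(trial)
                    hi = max(10.0, lam[l] * 10.0)
                    r = minimize_scalar(
                        f1, bounds=(0.0, hi), method="bounded",
                        options={"xatol": 1e-11},
                    )
                    if r.fun <= f1(lam[l]):
                        lam[l] = r.x
            # values within solver tolerance of zero are boundary solutions
            lam[lam < 1e-9] = 0.0
            if not np.isfinite(self.profiled_neg2reml(lam)):
                raise ConvergenceError("REML optimisation diverged", trace)

        beta, A, quad, logdetV0, logdetA = self._solve(lam)
        sigma2 = quad / (n - p)
        cov_beta = sigma2 * np.linalg.inv(A)
        vc = {name: float(lam[l] * sigma2) for l, name in enumerate(self.names)}
        boundary = {name: bool(lam[l] == 0.0) for l, name in enumerate(self.names)}
        return LMMFit(
            beta=beta, cov_beta=cov_beta, sigma2=float(sigma2),
            variance_components=vc, lam=lam, boundary=boundary,
            neg2_reml=float((n - p) * np.log(sigma2) + logdetV0 + logdetA),
            n_obs=n, n_params=p, trace=trace,
        )

    # -- Satterthwaite -------------------------------------------------------

    def _cvc(self, c: np.ndarray, theta: np.ndarray) -> float:
        """f(theta) = c' Cov(beta; theta) c."""
        sigma2 = theta[-1]
        lam = np.clip(theta[:-1], 0.0, None) / sigma2
        _, A, _, _, _ = self._solve(lam)
        x = np.linalg.solve(A, c)
        return float(sigma2 * (c @ x))

    def satterthwaite_df(self, fit: LMMFit, c: np.ndarray) -> float:
        """Satterthwaite denominator df for the contrast c' beta.

        Variance components estimated on the zero boundary are held fixed
        (standard practice); if every component is on the boundary the model
        is effectively OLS and the residual df is returned.
        """
        c = np.asarray(c, float)
        theta = np.append(
            np.array([fit.variance_components[nm] for nm in self.names]),
            fit.sigma2,
        )
        free = [i for i in range(self.d) if theta[i] > 0.0] + [self.d]
        if len(free) == 1 and self.d > 0 and all(
            fit.boundary[nm] for nm in self.names
        ):
            return float(fit.df_residual)

        f0 = self._cvc(c, theta)
        scale = np.maximum(np.abs(theta[free]), 1e-8 * max(theta[-1], 1e-12))
        h = 1e-4 * scale

        # gradient of f in the free variance parameters
        g = np.zeros(len(free))
        for j, i in enumerate(free):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[j]
            tm[i] = max(tm[i] - h[j], 0.0 if i < self.d else tm[i] * 0.5)
            g[j] = (self._cvc(c, tp) - self._cvc(c, tm)) / (tp[i] - tm[i])

        # observed information of -2 REML ll -> Var(theta) ~ 2 H^-1
        m = len(free)
        H = np.zeros((m, m))
        f_base = self.neg2reml_full(theta)
        for j, i in enumerate(free):
            for k, i2 in enumerate(free[: j + 1]):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[i] += h[j]; tpp[i2] += h[k]
                tpm[i] += h[j]; tpm[i2] -= h[k]
                tmp[i] -= h[j]; tmp[i2] += h[k]
                tmm[i] -= h[j]; tmm[i2] -= h[k]
                if min(tpm[i2], tmp[i], tmm[i], tmm[i2]) < 0:
                    # one-sided fallback at the boundary
                    if j == k:
                        t1 = _bump(theta, ((i, h[j]),))
                        t2 = _bump(theta, ((i, 2 * h[j]),))
                        H[j, k] = (
                            self.neg2reml_full(t2)
                            - 2 * self.neg2reml_full(t1) + f_base
                        ) / (h[j] ** 2)
                    else:
                        t12 = _bump(theta, ((i, h[j]), (i2, h[k])))
                        t1 = _bump(theta, ((i, h[j]),))
                        t2 = _bump(theta, ((i2, h[k]),))
                        H[j, k] = H[k, j] = (
                            self.neg2reml_full(t12) - self.neg2reml_full(t1)
                            - self.neg2reml_full(t2) + f_base
                        ) / (h[j] * h[k])
                    continue
                val = (
                    self.neg2reml_full(tpp) - self.neg2reml_full(tpm)
                    - self.neg2reml_full(tmp) + self.neg2reml_full(tmm)
                ) / (4 * h[j] * h[k])
                H[j, k] = H[k, j] = val

        try:
            var_theta = 2.0 * np.linalg.pinv(H)
            denom = float(g @ var_theta @ g)
        except np.linalg.LinAlgError:
            denom = 0.0
        if denom <= 0 or not np.isfinite(denom):
            return float(fit.df_residual)
        df = 2.0 * f0**2 / denom
        return float(np.clip(df, 1.0, fit.df_residual))


def _bump(theta, bumps):
    t = theta.copy()
    for i, hh in bumps:
        t[i] += hh
    return t
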