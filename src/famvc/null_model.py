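"""Null linear mixed model y = Xβ + δ (+ α) + ε fitted by ML or REML.

Under the null hypothesis of no region effect the phenotype covariance is
V0 = A σδ² (+ C σα²) + I σε² with A the background genetic similarity (GRM or
2Φ) and C the optional shared-household matrix.  The model is presented
statsmodels-style: :class:`PolygenicModel` holds the data, ``fit`` returns a
:class:`PolygenicResults` carrying the estimates, V0/P0 operators and the
maximised (restricted) log-likelihood.

Two fitting paths are used.  Without C the likelihood is profiled on the
variance ratio γ = σδ²/σε² after a one-time eigendecomposition of A, leaving
a robust 1-D bounded search.  With C (or when forced) a quasi-Newton search
runs on log-variances with blockwise Cholesky solves per evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError, DimensionError
from .linalg import BlockDiag, Dense, as_structure
from .relatedness import RelatednessSet

logger = logging.getLogger(__name__)

__all__ = ["PolygenicModel", "PolygenicResults", "fit_null", "dV_deta"]

_LOG2PI = float(np.log(2.0 * np.pi))


class PolygenicModel:
    """Polygenic null model for a quantitative trait.

    Parameters
    ----------
    y : array (q,)
        Phenotype vector.
    X : array (q, m) or None
        Covariates; an intercept column is appended unless already constant
        after centering.  With ``center=True`` (default) y and the covariate
        columns are mean-centered and only the centered design is used.
    rel : RelatednessSet
        Background structures A (and optional C) aligned to the phenotype.
    """

    def __init__(self, y, X=None, rel: RelatednessSet = None, center=True):
        y = np.asarray(y, dtype=float).ravel()
        q = y.shape[0]
        if rel is None:
            raise ValueError("a RelatednessSet is required")
        if rel.A.shape[0] != q:
            raise DimensionError("relatedness dimension does not match phenotype")
        if center:
            y = y - y.mean()
        if X is None:
            X = np.ones((q, 1))
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[0] != q:
                raise DimensionError("covariate rows do not match phenotype length")
            if center:
                X = X - X.mean(axis=0)
                X = X[:, np.ptp(X, axis=0) > 0]  # drop constants made zero
            X = np.column_stack([np.ones(q), X])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        self.y = y
        self.X = X
        self.rel = rel

    @classmethod
    def from_dataframe(cls, df, trait, covariates=(), rel=None, sample_col=None, **kw):
        """Build from a phenotype/covariate table aligned to ``rel.samples``."""
        if sample_col is not None:
            df = df.set_index(sample_col)
        if rel is not None:
            df = df.loc[rel.samples]
        y = df[trait].to_numpy(dtype=float)
        X = df[list(covariates)].to_numpy(dtype=float) if covariates else None
        return cls(y, X, rel=rel, **kw)

    # ------------------------------------------------------------------

    def fit(self, method="reml", include_household=None, max_iter=200,
            tol=1e-8, force_generic=False) -> "PolygenicResults":
        """Maximise the (restricted) likelihood over the variance components.

        ``include_household`` defaults to True when the relatedness set
        carries a C matrix.  ``force_generic`` routes a 2-component model
        through the quasi-Newton path (diagnostic cross-check of the 1-D
        profile optimiser).
        """
        method = method.lower()
        if method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")
        use_c = self.rel.C is not None if include_household is None else include_household
        if use_c and self.rel.C is None:
            raise ValueError("household matrix requested but absent from RelatednessSet")
        if use_c or force_generic:
            return self._fit_generic(method, max_iter, tol, use_c=use_c)
        return self._fit_profile(method, max_iter, tol)

    # -- 1-D profile path (A only) -------------------------------------

    def _fit_profile(self, method, max_iter, tol):
        q = self.y.shape[0]
        p = self.X.shape[1]
        w, U = self.rel.A.eigh()
        w = np.clip(w, 0.0, None)  # numerical PSD repair
        ystar = U.t_matmul(self.y)
        Xstar = U.t_matmul(self.X)

        dof = q - p if method == "reml" else q

        def neg_profile(log_gamma):
            gamma = np.exp(log_gamma)
            d = gamma * w + 1.0
            Xw = Xstar / d[:, None]
            XtWX = Xstar.T @ Xw
            XtWy = Xw.T @ ystar
            beta = np.linalg.solve(XtWX, XtWy)
            r = ystar - Xstar @ beta
            rss = float(np.sum(r * r / d))
            s2e = rss / dof
            # log|V| = q log s2e + Σ log d; r'V⁻¹r = rss/s2e = dof at the
            # profiled s2e; REML adds −½log|X'V⁻¹X|.
            ll = -0.5 * (np.sum(np.log(d)) + q * np.log(s2e) + dof
                         + dof * _LOG2PI)
            if method == "reml":
                sign, ld = np.linalg.slogdet(XtWX)
                ll -= 0.5 * (ld - p * np.log(s2e))
            return -ll

        res = optimize.minimize_scalar(neg_profile, bounds=(-15.0, 15.0),
                                       method="bounded",
                                       options={"xatol": 1e-10, "maxiter": max_iter})
        log_gamma = float(res.x)
        gamma = np.exp(log_gamma)
        boundary = log_gamma <= -15.0 + 1e-6 or log_gamma >= 15.0 - 1e-6
        d = gamma * w + 1.0
        Xw = Xstar / d[:, None]
        XtWX = Xstar.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ ystar)
        r = ystar - Xstar @ beta
        s2e = float(np.sum(r * r / d)) / dof
        s2d = gamma * s2e
        if boundary:
            if gamma < 1.0:
                s2d = 0.0
            logger.warning("variance ratio hit the search boundary; "
                           "components may not be separately identifiable")
        loglik = -neg_profile(log_gamma)
        return self._build_results(method, beta, s2d, None, s2e,
                                   loglik, bool(res.success), boundary)

    # -- generic path (A + C) ------------------------------------------

    def _fit_generic(self, method, max_iter, tol, use_c=True, start=None):
        q = self.y.shape[0]
        p = self.X.shape[1]
        A, C = self.rel.A, self.rel.C
        var_y = float(np.var(self.y))
        structs = [A, C] if use_c else [A]
        n_par = len(structs) + 1
        dof = q - p if method == "reml" else q

        def neg_loglik(theta):
            s2 = np.exp(theta)
            V = A.combine(list(s2[:-1]), structs, diag=s2[-1])
            try:
                ld = V.logdet()
            except np.linalg.LinAlgError:
                return 1e12
            VX = V.solve(self.X)
            XtVX = self.X.T @ VX
            beta = np.linalg.solve(XtVX, VX.T @ self.y)
            r = self.y - self.X @ beta
            quad = float(r @ V.solve(r))
            ll = -0.5 * (ld + quad + dof * _LOG2PI)
            if method == "reml":
                sign, ldx = np.linalg.slogdet(XtVX)
                ll -= 0.5 * ldx
            return -ll

        if start is None:
            base = np.array([0.3, 0.1, 0.6]) if use_c else np.array([0.4, 0.6])
            start = np.log(base * max(var_y, 1e-8))
        lo = np.log(1e-10 * max(var_y, 1e-8))
        hi = np.log(1e4 * max(var_y, 1e-8))
        # ftol is scaled by |f| internally; keep it tight so variance
        # components resolve to ~1e-4 relative even for large |loglik|
        res = optimize.minimize(neg_loglik, start, method="L-BFGS-B",
                                bounds=[(lo, hi)] * n_par,
                                options={"maxiter": max_iter, "ftol": 1e-13,
                                         "gtol": 1e-9})
        if not res.success and res.status != 1:
            raise ConvergenceError(f"variance optimisation failed: {res.message}")
        boundary = bool(np.any(res.x <= lo + 1e-6))
        s2 = np.where(res.x <= lo + 1e-6, 0.0, np.exp(res.x))
        V = A.combine(list(s2[:-1]), structs, diag=max(s2[-1], 1e-12))
        VX = V.solve(self.X)
        beta = np.linalg.solve(self.X.T @ VX, VX.T @ self.y)
        s2a = s2[1] if use_c else None
        return self._build_results(method, beta, s2[0], s2a, s2[-1],
                                   -res.fun, True, boundary)

    # ------------------------------------------------------------------

    def _build_results(self, method, beta, s2d, s2a, s2e, loglik, converged,
                       boundary):
        A, C = self.rel.A, self.rel.C
        coeffs, structs = [s2d], [A]
        if s2a is not None:
            coeffs.append(s2a)
            structs.append(C)
        V0 = A.combine(coeffs, structs, diag=max(s2e, 1e-12))
        if boundary:
            logger.warning("a variance component was estimated at the boundary 0; "
                           "score-test moment corrections assume interior estimates")
        return PolygenicResults(
            model=self, method=method.upper(), beta_hat=np.asarray(beta),
            sigma2_delta=float(s2d),
            sigma2_alpha=None if s2a is None else float(s2a),
            sigma2_eps=float(s2e), loglik=float(loglik),
            converged=bool(converged), boundary=bool(boundary),
            V0_struct=V0)


@dataclass
class PolygenicResults:
    """Fitted null model: estimates, covariance operators and diagnostics."""

    model: PolygenicModel
    method: str
    beta_hat: np.ndarray
    sigma2_delta: float
    sigma2_alpha: float | None
    sigma2_eps: float
    loglik: float
    converged: bool
    boundary: bool
    V0_struct: object
    _cache: dict = field(default_factory=dict, repr=False)

    # -- covariance operators ------------------------------------------

    def v0_solve(self, B):
        """V0⁻¹ B for a dense vector/matrix B."""
        return self.V0_struct.solve(B)

    @property
    def _vinv_X(self):
        if "VX" not in self._cache:
            self._cache["VX"] = self.v0_solve(self.model.X)
        return self._cache["VX"]

    @property
    def _xtvx_inv(self):
        if "K" not in self._cache:
            X = self.model.X
            self._cache["K"] = np.linalg.inv(X.T @ self._vinv_X)
        return self._cache["K"]

    def p0_apply(self, B):
        """Projection P0 B = V0⁻¹B − V0⁻¹X (X'V0⁻¹X)⁻¹ X'V0⁻¹B."""
        VB = self.v0_solve(B)
        VX = self._vinv_X
        return VB - VX @ (self._xtvx_inv @ (self.model.X.T @ VB))

    @property
    def V0(self) -> np.ndarray:
        """Dense V0 (materialised on demand; intended for moderate q)."""
        return self.V0_struct.to_dense()

    @property
    def P0(self) -> np.ndarray:
        return self.p0_apply(np.eye(self.model.y.shape[0]))

    @property
    def resid(self) -> np.ndarray:
        """y − X β̂."""
        return self.model.y - self.model.X @ self.beta_hat

    @property
    def variance_params(self):
        """Nuisance variance estimates in derivative order (σδ², [σα²,] σε²)."""
        if self.sigma2_alpha is None:
            return np.array([self.sigma2_delta, self.sigma2_eps])
        return np.array([self.sigma2_delta, self.sigma2_alpha, self.sigma2_eps])

    def dV_deta(self):
        """∂V/∂η structures in parameter order: [A, (C,) I]."""
        A = self.model.rel.A
        mats = [A]
        if self.sigma2_alpha is not None:
            mats.append(self.model.rel.C)
        if isinstance(A, BlockDiag):
            mats.append(A.combine([], [], diag=1.0))
        else:
            mats.append(Dense(np.eye(A.shape[0])))
        return mats

    def summary(self) -> str:
        lines = [
            "Polygenic null model ({}), q = {}".format(self.method, len(self.model.y)),
            "-" * 46,
            f"log-likelihood        {self.loglik:12.4f}",
            f"sigma2_delta (A)      {self.sigma2_delta:12.6f}",
        ]
        if self.sigma2_alpha is not None:
            lines.append(f"sigma2_alpha (C)      {self.sigma2_alpha:12.6f}")
        lines.append(f"sigma2_eps   (I)      {self.sigma2_eps:12.6f}")
        h2 = self.sigma2_delta / max(self.sigma2_delta + (self.sigma2_alpha or 0.0)
                                     + self.sigma2_eps, 1e-300)
        lines.append(f"polygenic fraction    {h2:12.4f}")
        for k, b in enumerate(self.beta_hat):
            lines.append(f"beta[{k}]               {b:12.6f}")
        if self.boundary:
            lines.append("note: a variance component is at the boundary 0")
        return "\n".join(lines)


def fit_null(y, X=None, rel: RelatednessSet = None, method="reml", **kw) -> PolygenicResults:
    """Convenience wrapper: fit the polygenic null model."""
    return PolygenicModel(y, X, rel=rel).fit(method=method, **kw)


def dV_deta(fit: PolygenicResults):
    """Derivatives of V with respect to each variance nuisance parameter."""
    return fit.dV_deta()
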