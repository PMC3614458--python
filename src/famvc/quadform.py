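"""Tail probabilities for positively weighted sums of chi-square variables.

The score statistic T for a tested variance component is asymptotically
distributed as Q = Σ_i λ_i χ²_{1,i} with independent 1-df chi-squares and
non-negative weights λ_i.  Four ways of evaluating P(Q ≥ T):

* ``pvalue_empirical`` — Monte Carlo simulation of Q (add-one estimator);
* ``pvalue_satterthwaite`` — two-moment gamma / scaled-chi-square matching;
* ``pvalue_liu`` — three/four-moment matching to a (noncentral) chi-square,
  matching skewness and minimising the kurtosis difference;
* ``pvalue_davies`` — numerical inversion of the characteristic function
  (Gil-Pelaez quadrature), the reference method.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

__all__ = [
    "pvalue_empirical",
    "pvalue_satterthwaite",
    "pvalue_liu",
    "pvalue_davies",
]


def _check_lambdas(lambdas):
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    if lam.size == 0:
        raise ValueError("eigenvalue vector is empty")
    if np.all(lam == 0):
        raise ValueError("all eigenvalues are zero (degenerate null distribution)")
    if np.any(lam < 0):
        raise ValueError("weights must be non-negative")
    return lam[lam > 0]


def pvalue_empirical(T, lambdas, n_sims=100_000, seed=None, chunk=2_000_000):
    """Monte Carlo p-value (1 + #{Q_sim ≥ T}) / (n_sims + 1).

    ``seed`` is required for reproducibility; draws are chunked so memory
    stays bounded for large ``n_sims``.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    if seed is None:
        raise ValueError("seed is required for the empirical p-value")
    lam = _check_lambdas(lambdas)
    rng = np.random.default_rng(seed)
    exceed = 0
    per_chunk = max(1, int(chunk // lam.size))
    done = 0
    while done < n_sims:
        m = min(per_chunk, n_sims - done)
        q = rng.chisquare(1.0, size=(m, lam.size)) @ lam
        exceed += int(np.count_nonzero(q >= T))
        done += m
    return (1.0 + exceed) / (n_sims + 1.0)


def pvalue_satterthwaite(T, muT, nuT, form="gamma"):
    """Two-moment approximation: Gamma(a, b) with a = μ²/ν, b = ν/μ.

    The scaled-chi-square form k·χ²_υ with k = ν/(2μ), υ = 2μ²/ν is the same
    distribution; both forms return identical p-values.
    """
    if muT <= 0 or nuT <= 0:
        raise ValueError("moments must be positive")
    if form == "gamma":
        a = muT ** 2 / nuT
        b = nuT / muT
        return float(stats.gamma.sf(T, a, scale=b))
    if form == "scaled_chi2":
        k = nuT / (2.0 * muT)
        df = 2.0 * muT ** 2 / nuT
        return float(stats.chi2.sf(T / k, df))
    raise ValueError(f"unknown Satterthwaite form {form!r}")


def pvalue_liu(T, lambdas):
    """Higher-moment approximation (Liu–Tang–Zhang style).

    Matches the first two cumulants and the skewness of Q to a shifted and
    scaled (possibly noncentral) chi-square, minimising the kurtosis
    difference; reduces to the exact chi-square when all weights are equal.
    """
    lam = _check_lambdas(lambdas)
    c1 = lam.sum()
    c2 = (lam ** 2).sum()
    c3 = (lam ** 3).sum()
    c4 = (lam ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2.0 * delta
    else:
        # skewness matched exactly by a central chi-square
        delta = 0.0
        a = 1.0 / s1
        df = 1.0 / s1 ** 2
    mu_q = c1
    sigma_q = np.sqrt(2.0 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(df + 2.0 * delta)
    t_star = (T - mu_q) / sigma_q
    x = t_star * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def _gil_pelaez_integrals(T, lam, accuracy):
    """∫_0^∞ sin(θ(u)) / (u ρ(u)) du with θ = ½Σ atan(λu) − ½Tu,
    ρ = Π (1 + λ²u²)^{1/4}, split at a scale point; the tail uses QUADPACK's
    oscillatory Fourier weights against the linear phase −Tu/2."""

    def log_rho(u):
        return 0.25 * np.sum(np.log1p((lam * u) ** 2))

    def phi(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def integrand(u):
        if u == 0.0:
            return 0.5 * (lam.sum() - T)
        return np.sin(phi(u) - 0.5 * T * u) * np.exp(-log_rho(u)) / u

    # scale so the head interval covers the bulk of the damping
    c = 1.0 / max(lam.max(), 1e-300)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        head, err_h = integrate.quad(integrand, 0.0, c,
                                     epsabs=accuracy, epsrel=1e-12, limit=500)
        # sin(φ − Tu/2) = sinφ cos(Tu/2) − cosφ sin(Tu/2)
        if T > 0:
            t1, e1 = integrate.quad(lambda u: np.sin(phi(u)) * np.exp(-log_rho(u)) / u,
                                    c, np.inf, weight="cos", wvar=0.5 * T,
                                    epsabs=accuracy, limit=500)
            t2, e2 = integrate.quad(lambda u: np.cos(phi(u)) * np.exp(-log_rho(u)) / u,
                                    c, np.inf, weight="sin", wvar=0.5 * T,
                                    epsabs=accuracy, limit=500)
            tail = t1 - t2
            err_t = e1 + e2
        else:
            tail, err_t = integrate.quad(integrand, c, np.inf,
                                         epsabs=accuracy, limit=500)
    return head + tail, err_h + err_t


def pvalue_davies(T, lambdas, accuracy=1e-9):
    """P(Σ λ_i χ²_1 ≥ T) by numerical characteristic-function inversion.

    Uses the Gil-Pelaez formula P = ½ + (1/π)∫_0^∞ Im[e^{-iuT} φ(u)]/u du
    evaluated by adaptive quadrature to the requested absolute accuracy.
    Falls back to the moment-matching approximation on inversion failure.
    """
    lam = _check_lambdas(lambdas)
    if T <= 0:
        return 1.0
    try:
        integral, err = _gil_pelaez_integrals(T, lam, accuracy)
        p = 0.5 + integral / np.pi
        if not np.isfinite(p) or err / np.pi > max(10 * accuracy, 1e-6):
            raise RuntimeError(f"inversion error estimate too large ({err:.2e})")
    except Exception as exc:  # pragma: no cover - defensive fallback
        logger.warning("characteristic-function inversion failed (%s); "
                       "falling back to moment matching", exc)
        return pvalue_liu(T, lam)
    return float(min(max(p, 0.0), 1.0))
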