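"""Variance-component score test for a genomic region.

Tests H0: σg² = 0 in V(y) = S σg² + A σδ² (+ C σα²) + I σε².  The score for
σg² at the null fit is

    U = −½ tr(V0⁻¹S) + ½ (y − Xβ̂)' V0⁻¹ S V0⁻¹ (y − Xβ̂),

and the test statistic is the quadratic part T = (y − Xβ̂)' M (y − Xβ̂) with
M = ½ V0⁻¹ S V0⁻¹ (ML) or ½ P0 S P0 (REML, with P0 the projection matrix).
Under H0, T ~ Σ λ_i χ²_{1,i} where the λ_i are the ordered nonzero
eigenvalues of V0^{1/2} M V0^{1/2}; p-values come from the methods in
:mod:`famvc.quadform`.  When S = F F' is low rank all computations contract
through F, so cost scales with the variant count rather than q².
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import quadform
from .exceptions import DimensionError
from .kernels import SimilarityMatrix, linear_similarity, weighted_ibs_kernel, beta_weights
from .genotype_io import GenotypeMatrix, standardize
from .linalg import trace_mul, trace_quad
from .null_model import PolygenicResults, fit_null
from .relatedness import RelatednessSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTestResult",
    "score_statistic",
    "null_eigenvalues",
    "moments",
    "test_region",
    "RegionTest",
]

P_VALUE_METHODS = ("davies", "satterthwaite_gamma", "satterthwaite_chi2",
                   "liu", "empirical")


@dataclass
class ScoreTestResult:
    """Score statistic, null-distribution summaries and p-values."""

    T: float
    U: float
    eigenvalues: np.ndarray
    muT: float
    nuT: float
    nuT_corrected: float
    p_values: dict
    r_used: int
    method: str
    n_variants: int

    def summary(self) -> str:
        lines = [
            f"Region VC score test ({self.method}, {self.n_variants} variants)",
            "-" * 52,
            f"T statistic        {self.T:14.6f}",
            f"score U            {self.U:14.6f}",
            f"mu_T               {self.muT:14.6f}",
            f"nu_T (raw)         {self.nuT:14.6f}",
            f"nu_T (corrected)   {self.nuT_corrected:14.6f}",
            f"eigenvalues used   {self.r_used:14d}",
        ]
        for name, p in self.p_values.items():
            lines.append(f"p ({name:<18s}) {p:12.4e}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "T": self.T, "U": self.U, "muT": self.muT, "nuT": self.nuT,
            "nuT_corrected": self.nuT_corrected, "r_used": self.r_used,
            "method": self.method, "n_variants": self.n_variants,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "p_values": {k: float(v) for k, v in self.p_values.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# ---------------------------------------------------------------------------
# core contractions


def _factor_images(fit: PolygenicResults, F: np.ndarray):
    """Return (W F, W r) where W = V0⁻¹ (ML) or P0 (REML), cached on the fit.

    The cache is keyed by object identity of F so that the statistic,
    eigenvalues and moments of one region share a single projection.
    """
    apply_w = fit.p0_apply if fit.method == "REML" else fit.v0_solve
    cache = fit._cache.setdefault("score_images", [])
    WF = next((img for Fc, img in cache if Fc is F), None)
    if WF is None:
        WF = apply_w(F)
        cache.append((F, WF))
        del cache[:-4]  # bound memory across many regions
    if "wr" not in fit._cache:
        # P0 y = P0 r since P0 X = 0
        src = fit.model.y if fit.method == "REML" else fit.resid
        fit._cache["wr"] = apply_w(src)
    return WF, fit._cache["wr"]


def _vinv_struct(fit: PolygenicResults):
    if "Vinv" not in fit._cache:
        fit._cache["Vinv"] = fit.V0_struct.inv()
    return fit._cache["Vinv"]


def _b_matrix(fit: PolygenicResults, S: SimilarityMatrix):
    """½ F' W F whose eigenvalues are those of V0^{1/2} M V0^{1/2}."""
    F = S.factor
    WF, _ = _factor_images(fit, F)
    return 0.5 * (F.T @ WF), F, WF


def score_statistic(y, X, fit: PolygenicResults, S: SimilarityMatrix):
    """Score statistic T and full score U = T − ½tr(W S) at the null fit.

    ``y``/``X`` may be None to use the fit's own data (they must otherwise
    match the fit).
    """
    if y is not None and not np.allclose(np.asarray(y, float) - np.mean(y),
                                         fit.model.y, atol=1e-8):
        raise DimensionError("y does not match the data the null model was fitted to")
    F = S.factor
    if F.shape[0] != fit.model.y.shape[0]:
        raise DimensionError("similarity dimension does not match phenotype")
    WF, wr = _factor_images(fit, F)
    T = 0.5 * float(np.sum((F.T @ wr) ** 2))
    trWS = float(np.sum(F * WF))
    return T, T - 0.5 * trWS


def null_eigenvalues(fit: PolygenicResults, S: SimilarityMatrix, r=None) -> np.ndarray:
    """Ordered nonzero eigenvalues λ_i of V0^{1/2} M V0^{1/2}.

    Values below 1e-10·λ_max are dropped as numerical zeros; with ``r`` only
    the r largest are returned.
    """
    B, _, _ = _b_matrix(fit, S)
    lam = np.linalg.eigvalsh(B)[::-1]
    if lam.size == 0:
        return lam
    lam = lam[lam > 1e-10 * max(lam[0], 0.0)]
    if r is not None:
        lam = lam[:r]
    return lam


def moments(fit: PolygenicResults, S: SimilarityMatrix, correct="partial_information"):
    """First two moments (μ_T, ν_T) of T under H0.

    μ_T = ½tr(W S), ν_T = ½tr((W S)²) with W = V0⁻¹ (ML) or P0 (REML).  With
    ``correct='partial_information'`` the variance is replaced by the
    efficient information I_τ = I_ττ − I_τη I_ηη⁻¹ I_ητ, accounting for the
    estimated nuisance variance parameters.
    """
    F = S.factor
    WF, _ = _factor_images(fit, F)
    muT = 0.5 * float(np.sum(F * WF))
    FtWF = F.T @ WF
    i_tt = 0.5 * float(np.sum(FtWF * FtWF.T))
    nuT = i_tt
    if correct == "none":
        return muT, nuT
    if correct != "partial_information":
        raise ValueError(f"unknown correction {correct!r}")
    mats = fit.dV_deta()
    k = len(mats)
    # I_tau_eta[j] = ½ tr(W S W D_j) = ½ tr((WF)' D_j (WF))
    i_te = np.array([0.5 * trace_quad(D, WF) for D in mats])
    i_ee = np.empty((k, k))
    if fit.method == "REML":
        Vinv = _vinv_struct(fit)
        X = fit.model.X
        K = fit._xtvx_inv
        L = np.linalg.cholesky(K)
        Q = fit._vinv_X @ L  # P0 = V0⁻¹ − Q Q'
        WD = [Vinv.struct_mul(D) for D in mats]
        DQ = [D.matmul(Q) for D in mats]
        for i in range(k):
            for j in range(i, k):
                t_full = trace_mul(WD[i], WD[j])
                # cross terms: tr(QQ' D_i V0⁻¹ D_j) and tr(QQ' D_i QQ' D_j)
                a_ij = float(np.sum(DQ[i] * fit.v0_solve(DQ[j])))
                QtDiQ = Q.T @ DQ[i]
                QtDjQ = Q.T @ DQ[j]
                t_qq = float(np.sum(QtDiQ * QtDjQ.T))
                val = 0.5 * (t_full - 2.0 * a_ij + t_qq)
                i_ee[i, j] = i_ee[j, i] = val
    else:
        Vinv = _vinv_struct(fit)
        WD = [Vinv.struct_mul(D) for D in mats]
        for i in range(k):
            for j in range(i, k):
                i_ee[i, j] = i_ee[j, i] = 0.5 * trace_mul(WD[i], WD[j])
    try:
        corr = float(i_te @ np.linalg.solve(i_ee, i_te))
    except np.linalg.LinAlgError:
        logger.warning("nuisance information matrix singular; "
                       "using uncorrected variance")
        return muT, nuT
    nu_corr = i_tt - corr
    if nu_corr <= 0:
        logger.warning("partial-information variance non-positive; "
                       "using uncorrected variance")
        return muT, nuT
    return muT, nu_corr


# ---------------------------------------------------------------------------
# orchestration


class RegionTest:
    """Score test of a region similarity against a fitted (or fittable) null.

    statsmodels-style facade: construct with data, ``fit()`` returns a
    :class:`ScoreTestResult`.
    """

    def __init__(self, y, X=None, *, genotypes: GenotypeMatrix = None,
                 similarity: SimilarityMatrix = None,
                 rel: RelatednessSet = None, null_fit: PolygenicResults = None):
        if similarity is None and genotypes is None:
            raise ValueError("provide genotypes or a similarity matrix")
        self.y = y
        self.X = X
        self.genotypes = genotypes
        self.similarity = similarity
        self.rel = rel
        self.null_fit = null_fit

    def fit(self, method="reml", kernel="linear", weights=None,
            p_methods=("davies", "satterthwaite_gamma"), correct="partial_information",
            n_sims=100_000, seed=None, r=None) -> ScoreTestResult:
        fit = self.null_fit
        if fit is None:
            fit = fit_null(self.y, self.X, rel=self.rel, method=method)
        S = self.similarity
        if S is None:
            if kernel == "linear":
                S = linear_similarity(standardize(self.genotypes))
            elif kernel in ("wibs", "weighted_ibs"):
                w = None
                if weights is not None:
                    a, b = weights
                    w = beta_weights(self.genotypes.maf, a, b)
                S = weighted_ibs_kernel(self.genotypes, w)
            else:
                raise ValueError(f"unknown kernel {kernel!r}")
        if fit.model.y.shape[0] != S.shape[0]:
            raise DimensionError("similarity dimension does not match phenotype")

        T, U = score_statistic(None, None, fit, S)
        lam = null_eigenvalues(fit, S, r=r)
        muT, nuT_raw = moments(fit, S, correct="none")
        _, nuT_corr = moments(fit, S, correct=correct) if correct != "none" \
            else (muT, nuT_raw)

        pvals = {}
        for name in p_methods:
            if name == "davies":
                pvals[name] = quadform.pvalue_davies(T, lam)
            elif name == "satterthwaite_gamma":
                pvals[name] = quadform.pvalue_satterthwaite(T, muT, nuT_corr, "gamma")
            elif name == "satterthwaite_chi2":
                pvals[name] = quadform.pvalue_satterthwaite(T, muT, nuT_corr,
                                                            "scaled_chi2")
            elif name == "liu":
                pvals[name] = quadform.pvalue_liu(T, lam)
            elif name == "empirical":
                pvals[name] = quadform.pvalue_empirical(T, lam, n_sims=n_sims,
                                                        seed=seed)
            else:
                raise ValueError(f"unknown p-value method {name!r}")
        return ScoreTestResult(T=float(T), U=float(U), eigenvalues=lam,
                               muT=float(muT), nuT=float(nuT_raw),
                               nuT_corrected=float(nuT_corr), p_values=pvals,
                               r_used=int(lam.size), method=fit.method,
                               n_variants=S.n_variants)


def test_region(y, X=None, genotypes=None, similarity=None, rel=None,
                null_fit=None, **fit_kw) -> ScoreTestResult:
    """One-call orchestration: null fit → similarity → statistic → p-values."""
    rt = RegionTest(y, X, genotypes=genotypes, similarity=similarity,
                    rel=rel, null_fit=null_fit)
    return rt.fit(**fit_kw)


test_region.__test__ = False  # not a pytest item when star-imported
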