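"""Region similarity matrices for the tested variance component.

The tested component models var(y) += S·σg² where S measures region-level
genetic similarity between individuals.  Three constructions are provided:

* linear: S = Z Z' / n on standardized genotypes (the default);
* weighted IBS kernel: K_ij = Σ_l w_l (2 − |s_il − s_jl|), optionally with
  beta-density weights emphasising rare variants;
* haplotype sharing: (S_h)_ij sums a haplotype-level similarity s(h, k) over
  the four cross-individual haplotype pairs.

All are symmetric PSD (up to numerical clipping).  Low-rank factors are kept
when available so the score test can work in the n-dimensional variant space
rather than the q-dimensional sample space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DimensionError
from .genotype_io import GenotypeMatrix, StandardizedGenotypes

__all__ = [
    "SimilarityMatrix",
    "linear_similarity",
    "beta_weights",
    "weighted_ibs_kernel",
    "haplotype_similarity",
    "burden_similarity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric PSD region similarity S, optionally as a low-rank factor.

    Exactly one of ``dense``/``factor`` may be omitted; ``S = F F'`` when the
    factor F (q × k) is stored.
    """

    kind: str
    n_variants: int
    dense: np.ndarray = None
    _factor: np.ndarray = None

    @property
    def shape(self):
        if self.dense is not None:
            return self.dense.shape
        return (self._factor.shape[0], self._factor.shape[0])

    @property
    def matrix(self) -> np.ndarray:
        if self.dense is None:
            self.dense = self._factor @ self._factor.T
        return self.dense

    @property
    def factor(self) -> np.ndarray:
        """A factor F with S = F F' (computed by eigendecomposition if needed)."""
        if self._factor is None:
            w, V = np.linalg.eigh(self.dense)
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ValueError(f"similarity matrix not PSD (min eig {w.min():.3g})")
            keep = w > max(w.max(), 0.0) * 1e-12
            self._factor = V[:, keep] * np.sqrt(w[keep])
        return self._factor


def linear_similarity(Z: StandardizedGenotypes | np.ndarray) -> SimilarityMatrix:
    """Linear similarity S = Z Z' / n on standardized genotypes."""
    M = Z.Z if isinstance(Z, StandardizedGenotypes) else np.asarray(Z, dtype=float)
    n = M.shape[1]
    if n < 1:
        raise DimensionError("need at least one variant")
    return SimilarityMatrix(kind="linear", n_variants=n, _factor=M / np.sqrt(n))


def burden_similarity(b: np.ndarray) -> SimilarityMatrix:
    """Rank-1 similarity b b' from a per-individual burden score."""
    b = np.asarray(b, dtype=float)
    return SimilarityMatrix(kind="linear", n_variants=1, _factor=b[:, None])


def beta_weights(freqs, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density variant weights w_l = Beta(p_l; a, b).

    With a = b = 1 all weights are 1; small ``a`` with large ``b`` sharply
    up-weights rare variants.
    """
    p = np.asarray(freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("beta weights require frequencies strictly inside (0, 1)")
    if a <= 0 or b <= 0:
        raise ValueError("beta shapes must be positive")
    return stats.beta.pdf(p, a, b)


def weighted_ibs_kernel(G: GenotypeMatrix | np.ndarray, weights=None,
                        squared: bool = False) -> SimilarityMatrix:
    """Weighted identity-by-state kernel K_ij = Σ_l w_l (2 − |s_il − s_jl|).

    ``squared=True`` applies w_l² instead (the convention of some kernel
    association tools); the default enters the weights linearly.
    """
    S = G.G if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    q, n = S.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != n:
            raise DimensionError("weights length does not match variant count")
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
    if squared:
        w = w ** 2
    K = np.zeros((q, q))
    # accumulate per variant: w_l (2 - |s_i - s_j|)
    for l in range(n):
        col = S[:, l]
        K += w[l] * (2.0 - np.abs(col[:, None] - col[None, :]))
    lam_min = np.linalg.eigvalsh(K).min()
    if lam_min < -1e-8 * max(abs(K).max(), 1.0):
        # clip tiny negative eigenvalues to keep K usable as a variance structure
        wv, V = np.linalg.eigh(K)
        K = (V * np.clip(wv, 0.0, None)) @ V.T
    return SimilarityMatrix(kind="weighted_ibs", n_variants=n, dense=K)


def match_proportion(h, k) -> float:
    """Default haplotype similarity: proportion of matching alleles."""
    h = np.asarray(h)
    k = np.asarray(k)
    return float(np.mean(h == k))


def haplotype_similarity(H, s=match_proportion) -> SimilarityMatrix:
    """Haplotype-sharing similarity (S_h)_ij = Σ over 4 haplotype pairs of s(h, k).

    ``H`` is a sequence of per-individual haplotype pairs (each pair two
    equal-length allele arrays over the region).  With the default
    match-proportion ``s`` this is four times the average allelic sharing.
    """
    pairs = [(np.asarray(a), np.asarray(b)) for a, b in H]
    L = {a.shape[0] for p in pairs for a in p}
    if len(L) != 1:
        raise DimensionError("haplotypes must all have equal length")
    q = len(pairs)
    Sh = np.zeros((q, q))
    for i in range(q):
        for j in range(i, q):
            val = sum(s(hi, hj) for hi in pairs[i] for hj in pairs[j])
            Sh[i, j] = Sh[j, i] = val
    return SimilarityMatrix(kind="haplotype", n_variants=int(next(iter(L))), dense=Sh)
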