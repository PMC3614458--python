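"""Structured symmetric matrices for mixed-model computations.

Family designs give variance-structure matrices (kinship 2Φ, household C,
identity) that are block diagonal under a family-sorted sample order, with
many small blocks of a handful of distinct sizes.  ``BlockDiag`` stores the
blocks batched by size so that solves, products, eigendecompositions and the
trace contractions needed by the score test run as vectorised batched numpy
operations instead of per-family Python loops.

Dense ndarrays (e.g. a genome-wide GRM) are supported through the same duck
API via ``Dense``; ``as_structure`` dispatches.
"""

from __future__ import annotations

import numpy as np


class BlockDiag:
    """Square block-diagonal matrix with blocks batched by size.

    Parameters
    ----------
    groups : list of (idx, data)
        ``idx`` is an ``(m, s)`` integer array of row/column indices for ``m``
        blocks of size ``s``; ``data`` is the matching ``(m, s, s)`` stack of
        blocks.  Indices across all groups must partition ``range(q)``.
    """

    def __init__(self, groups):
        self.groups = [(np.asarray(idx, dtype=np.intp), np.asarray(dat, dtype=float))
                       for idx, dat in groups]
        self.q = sum(idx.size for idx, _ in self.groups)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_blocks(cls, index_lists, blocks):
        """Build from per-block index lists and square blocks, batching by size."""
        by_size: dict[int, list] = {}
        for idx, blk in zip(index_lists, blocks):
            idx = np.asarray(idx, dtype=np.intp)
            blk = np.atleast_2d(np.asarray(blk, dtype=float))
            s = idx.size
            if blk.shape != (s, s):
                raise ValueError(f"block shape {blk.shape} does not match index size {s}")
            by_size.setdefault(s, []).append((idx, blk))
        groups = []
        for s, items in sorted(by_size.items()):
            idx = np.stack([i for i, _ in items])
            dat = np.stack([b for _, b in items])
            groups.append((idx, dat))
        return cls(groups)

    @classmethod
    def identity_like(cls, other):
        return other.combine([], [], diag=1.0)

    @property
    def shape(self):
        return (self.q, self.q)

    def copy_groups(self):
        return [(idx, dat.copy()) for idx, dat in self.groups]

    # -- conversions --------------------------------------------------------

    def to_dense(self):
        out = np.zeros((self.q, self.q))
        for idx, dat in self.groups:
            m, s = idx.shape
            rows = idx[:, :, None]
            cols = idx[:, None, :]
            out[rows, cols] = dat
        return out

    def diagonal(self):
        d = np.empty(self.q)
        for idx, dat in self.groups:
            d[idx] = np.einsum("mss->ms", dat)
        return d

    # -- algebra ------------------------------------------------------------

    def combine(self, coeffs, mats, diag=0.0):
        """Return Σ c_k M_k + diag·I as a BlockDiag over this partition.

        All ``mats`` must share this partition (group order and indices).
        ``self`` is used only for its partition.
        """
        groups = []
        for gi, (idx, _) in enumerate(self.groups):
            m, s = idx.shape
            acc = np.zeros((m, s, s))
            for c, M in zip(coeffs, mats):
                acc += c * M.groups[gi][1]
            if diag != 0.0:
                acc[:, np.arange(s), np.arange(s)] += diag
            groups.append((idx, acc))
        return BlockDiag(groups)

    def matmul(self, B):
        """Matrix product with a dense (q, k) array (or (q,) vector)."""
        B = np.asarray(B, dtype=float)
        vec = B.ndim == 1
        if vec:
            B = B[:, None]
        out = np.empty_like(B)
        for idx, dat in self.groups:
            m, s = idx.shape
            sub = B[idx.ravel()].reshape(m, s, -1)
            out[idx.ravel()] = np.matmul(dat, sub).reshape(m * s, -1)
        return out[:, 0] if vec else out

    def solve(self, B):
        """Solve self @ X = B for dense B of shape (q, k) or (q,)."""
        B = np.asarray(B, dtype=float)
        vec = B.ndim == 1
        if vec:
            B = B[:, None]
        out = np.empty_like(B)
        for idx, dat in self.groups:
            m, s = idx.shape
            sub = B[idx.ravel()].reshape(m, s, -1)
            if s == 1:
                sol = sub / dat
            else:
                sol = np.linalg.solve(dat, sub)
            out[idx.ravel()] = sol.reshape(m * s, -1)
        return out[:, 0] if vec else out

    def inv(self):
        groups = []
        for idx, dat in self.groups:
            if idx.shape[1] == 1:
                groups.append((idx, 1.0 / dat))
            else:
                groups.append((idx, np.linalg.inv(dat)))
        return BlockDiag(groups)

    def logdet(self):
        total = 0.0
        for idx, dat in self.groups:
            if idx.shape[1] == 1:
                total += np.sum(np.log(dat[:, 0, 0]))
            else:
                sign, ld = np.linalg.slogdet(dat)
                if np.any(sign <= 0):
                    raise np.linalg.LinAlgError("non positive definite block")
                total += np.sum(ld)
        return total

    def eigh(self):
        """Eigendecomposition; returns (eigenvalues (q,), U BlockDiag).

        ``U`` is block-orthogonal: ``U.t_matmul`` applies U'.
        """
        w = np.empty(self.q)
        groups = []
        for idx, dat in self.groups:
            m, s = idx.shape
            if s == 1:
                w[idx[:, 0]] = dat[:, 0, 0]
                groups.append((idx, np.ones_like(dat)))
            else:
                vals, vecs = np.linalg.eigh(dat)
                w[idx] = vals
                groups.append((idx, vecs))
        return w, BlockDiag(groups)

    def t_matmul(self, B):
        """Product self.T @ B for dense B."""
        B = np.asarray(B, dtype=float)
        vec = B.ndim == 1
        if vec:
            B = B[:, None]
        out = np.empty_like(B)
        for idx, dat in self.groups:
            m, s = idx.shape
            sub = B[idx.ravel()].reshape(m, s, -1)
            out[idx.ravel()] = np.matmul(dat.transpose(0, 2, 1), sub).reshape(m * s, -1)
        return out[:, 0] if vec else out

    def min_eigenvalue(self):
        w = np.empty(self.q)
        for idx, dat in self.groups:
            if idx.shape[1] == 1:
                w[idx[:, 0]] = dat[:, 0, 0]
            else:
                w[idx] = np.linalg.eigvalsh(dat)
        return float(w.min())

    def struct_mul(self, other):
        """Blockwise product self @ other over a shared partition -> BlockDiag."""
        groups = []
        for (idx, a), (_, b) in zip(self.groups, other.groups):
            groups.append((idx, np.matmul(a, b)))
        return BlockDiag(groups)

    def trace(self):
        return float(sum(np.einsum("mss->", dat) for _, dat in self.groups))


class Dense:
    """Dense symmetric matrix with the same duck API as BlockDiag."""

    def __init__(self, M):
        self.M = np.asarray(M, dtype=float)
        self.q = self.M.shape[0]

    @property
    def shape(self):
        return self.M.shape

    def to_dense(self):
        return self.M

    def diagonal(self):
        return np.diagonal(self.M).copy()

    def combine(self, coeffs, mats, diag=0.0):
        acc = np.zeros_like(self.M)
        for c, M in zip(coeffs, mats):
            acc += c * M.to_dense()
        if diag != 0.0:
            acc[np.diag_indices_from(acc)] += diag
        return Dense(acc)

    def matmul(self, B):
        return self.M @ B

    t_matmul_dense = None

    def t_matmul(self, B):
        return self.M.T @ B

    def solve(self, B):
        return np.linalg.solve(self.M, B)

    def inv(self):
        return Dense(np.linalg.inv(self.M))

    def logdet(self):
        sign, ld = np.linalg.slogdet(self.M)
        if sign <= 0:
            raise np.linalg.LinAlgError("matrix not positive definite")
        return float(ld)

    def eigh(self):
        w, V = np.linalg.eigh(self.M)
        return w, Dense(V)

    def min_eigenvalue(self):
        return float(np.linalg.eigvalsh(self.M).min())

    def struct_mul(self, other):
        return Dense(self.M @ other.to_dense())

    def trace(self):
        return float(np.trace(self.M))


def as_structure(M):
    """Wrap an ndarray as Dense; pass BlockDiag/Dense through."""
    if isinstance(M, (BlockDiag, Dense)):
        return M
    return Dense(np.asarray(M, dtype=float))


def trace_quad(D, G, H=None):
    """tr(G' D H) for dense (q, k) arrays G, H and structure D."""
    if H is None:
        H = G
    if isinstance(D, Dense):
        return float(np.sum(G * (D.M @ H)))
    total = 0.0
    for idx, dat in D.groups:
        m, s = idx.shape
        g = G[idx.ravel()].reshape(m, s, -1)
        h = H[idx.ravel()].reshape(m, s, -1)
        total += np.einsum("msk,msr,mrk->", g, dat, h)
    return float(total)


def trace_mul(D1, D2):
    """tr(D1 @ D2) for two structures over the same partition (or dense)."""
    if isinstance(D1, Dense) or isinstance(D2, Dense):
        return float(np.sum(D1.to_dense() * D2.to_dense().T))
    total = 0.0
    for (idx, a), (_, b) in zip(D1.groups, D2.groups):
        total += np.einsum("mab,mba->", a, b)
    return float(total)
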