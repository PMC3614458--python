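"""Background variance-structure matrices.

Two sources of expected phenotypic resemblance enter the null mixed model:
a genetic similarity matrix A — either a genome-wide GRM computed from
standardized genotypes, or twice the pedigree kinship matrix 2Φ — and an
optional shared-household indicator matrix C.  Both 2Φ and C are block
diagonal under a family-sorted sample order and are returned as
:class:`~famvc.linalg.BlockDiag` structures so downstream mixed-model code
scales linearly in the number of families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import PedigreeError
from .linalg import BlockDiag, as_structure

__all__ = ["Pedigree", "RelatednessSet", "grm", "kinship_matrix", "household_matrix"]


@dataclass
class Pedigree:
    """Pedigree records: family id, individual id, father, mother (0/None = founder)."""

    records: pd.DataFrame  # columns fid, iid, father, mother, sex (sex optional)

    def __post_init__(self):
        df = self.records.copy()
        for col in ("fid", "iid", "father", "mother"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree missing column {col!r}")
            df[col] = df[col].astype(str)
        df.loc[df["father"].isin(("0", "nan", "None", "")), "father"] = None
        df.loc[df["mother"].isin(("0", "nan", "None", "")), "mother"] = None
        if df["iid"].duplicated().any():
            raise PedigreeError("duplicate individual ids in pedigree")
        self.records = df.reset_index(drop=True)
        self._validate()

    @classmethod
    def from_fam(cls, path):
        """Read a LINKAGE/PLINK .fam-style whitespace table (FID IID PAT MAT [SEX])."""
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        df = df.iloc[:, :5]
        df.columns = ["fid", "iid", "father", "mother", "sex"][: df.shape[1]]
        return cls(df)

    @classmethod
    def from_tuples(cls, rows):
        """Build from (fid, iid, father, mother) tuples; None/'0' marks a founder."""
        df = pd.DataFrame(rows, columns=["fid", "iid", "father", "mother"])
        return cls(df)

    def _columns(self):
        df = self.records
        return (df["fid"].tolist(), df["iid"].tolist(),
                df["father"].tolist(), df["mother"].tolist())

    def _validate(self):
        fids, iids, fathers, mothers = self._columns()
        known = dict(zip(iids, fids))
        for fid, iid, fa, mo in zip(fids, iids, fathers, mothers):
            if (fa is None) != (mo is None):
                raise PedigreeError(f"{iid}: exactly one parent recorded")
            for p in (fa, mo):
                if p is not None:
                    if p not in known:
                        raise PedigreeError(f"{iid}: parent {p} not in pedigree")
                    if known[p] != fid:
                        raise PedigreeError(f"{iid}: parent {p} in a different family")
        # cycle check via topological ordering
        self._topological_order()

    def _topological_order(self):
        _, iids, fathers, mothers = self._columns()
        parents = {i: [p for p in (fa, mo) if p is not None]
                   for i, fa, mo in zip(iids, fathers, mothers)}
        order, state = [], {}

        def visit(i):
            if state.get(i) == 2:
                return
            if state.get(i) == 1:
                raise PedigreeError("pedigree contains a cycle")
            state[i] = 1
            for p in parents[i]:
                visit(p)
            state[i] = 2
            order.append(i)

        for i in parents:
            visit(i)
        return order

    @property
    def ids(self):
        return self.records["iid"].tolist()

    @property
    def families(self):
        """Mapping family id -> list of member ids, in record order."""
        out: dict[str, list] = {}
        for fid, iid in zip(self.records["fid"].tolist(),
                            self.records["iid"].tolist()):
            out.setdefault(fid, []).append(iid)
        return out


@dataclass
class RelatednessSet:
    """Variance-structure matrices aligned to one sample order.

    ``A`` is the background genetic similarity (GRM or 2Φ), ``C`` the optional
    0/1 shared-household matrix.  Either may be a dense ndarray or a
    :class:`BlockDiag`.
    """

    samples: list
    A: object
    C: object = None

    def __post_init__(self):
        self.A = as_structure(self.A)
        if self.C is not None:
            self.C = as_structure(self.C)
        q = len(self.samples)
        if self.A.shape != (q, q):
            raise PedigreeError("A dimension does not match sample count")
        lam_min = self.A.min_eigenvalue()
        if lam_min < -1e-8:
            raise PedigreeError(f"A is not PSD (min eigenvalue {lam_min:.3g})")


def grm(Zgw, exclude=()) -> np.ndarray:
    """Genome-wide genetic relationship matrix A = Z Z' / N.

    ``Zgw`` is a :class:`StandardizedGenotypes` over genome-wide SNPs;
    ``exclude`` names SNPs (e.g. the tested region) removed before averaging.
    """
    exclude = set(exclude)
    keep = [j for j, v in enumerate(Zgw.variant_ids) if v not in exclude]
    if not keep:
        raise ValueError("all genome-wide SNPs excluded from GRM")
    Z = Zgw.Z[:, keep]
    return Z @ Z.T / Z.shape[1]


def _family_kinship(members, father, mother):
    """Recursive kinship for one family, members in topological order.

    phi_ii = ½(1 + phi_{f,m}); phi_ij = ½(phi_{i,f(j)} + phi_{i,m(j)}).
    Founders are assumed non-inbred and mutually unrelated.
    """
    n = len(members)
    pos = {m: k for k, m in enumerate(members)}
    phi = np.zeros((n, n))
    for j, mj in enumerate(members):
        fa, mo = father[mj], mother[mj]
        if fa is None:
            phi[j, j] = 0.5
        else:
            phi[j, j] = 0.5 * (1.0 + phi[pos[fa], pos[mo]])
        for i in range(j):
            if fa is None:
                # j is a founder: unrelated to anyone it did not descend to yet
                phi[i, j] = phi[j, i] = 0.0
            else:
                val = 0.5 * (phi[i, pos[fa]] + phi[i, pos[mo]])
                phi[i, j] = phi[j, i] = val
    return phi


def kinship_matrix(ped: Pedigree, unrelated_ids=()):
    """Expected-relatedness matrix 2Φ as a BlockDiag, plus its sample order.

    Pedigree members come first (family-sorted, parents before children),
    then ``unrelated_ids`` as singleton blocks with diagonal 1.

    Returns
    -------
    samples : list of str
    A : BlockDiag
        2Φ over the returned order.
    """
    _, iids, fathers, mothers = ped._columns()
    father = dict(zip(iids, fathers))
    mother = dict(zip(iids, mothers))
    topo_rank = {i: k for k, i in enumerate(ped._topological_order())}

    samples, index_lists, blocks = [], [], []
    offset = 0
    for fid, members in ped.families.items():
        members = sorted(members, key=lambda i: topo_rank[i])
        phi = _family_kinship(members, father, mother)
        idx = np.arange(offset, offset + len(members))
        samples.extend(members)
        index_lists.append(idx)
        blocks.append(2.0 * phi)
        offset += len(members)
    for uid in unrelated_ids:
        samples.append(uid)
        index_lists.append(np.array([offset]))
        blocks.append(np.array([[1.0]]))
        offset += 1
    return samples, BlockDiag.from_blocks(index_lists, blocks)


def household_matrix(ped: Pedigree, unrelated_ids=()):
    """Shared-household matrix C: C_jk = 1 iff j, k share a family (C_jj = 1).

    Sample order matches :func:`kinship_matrix` so the two structures share a
    partition and can be combined blockwise.
    """
    topo_rank = {i: k for k, i in enumerate(ped._topological_order())}
    samples, index_lists, blocks = [], [], []
    offset = 0
    for fid, members in ped.families.items():
        members = sorted(members, key=lambda i: topo_rank[i])
        n = len(members)
        samples.extend(members)
        index_lists.append(np.arange(offset, offset + n))
        blocks.append(np.ones((n, n)))
        offset += n
    for uid in unrelated_ids:
        samples.append(uid)
        index_lists.append(np.array([offset]))
        blocks.append(np.array([[1.0]]))
        offset += 1
    return samples, BlockDiag.from_blocks(index_lists, blocks)
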