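"""Genotype containers, readers and region-level summaries.

Genotypes are held as additive minor-allele counts (0/1/2, ``nan`` for
missing) in a samples × variants matrix.  Readers orient every variant to its
minor allele (counted-allele frequency ≤ 0.5), skip multiallelic records and
compute in-sample allele frequencies.  Standardization maps a count s with
frequency f to z = (s − 2f) / sqrt(2 f (1 − f)), the scaling under which the
cross-product of genotype rows estimates genetic relatedness.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DimensionError, EmptyRegionError, FamvcError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "StandardizedGenotypes",
    "read_genotypes",
    "compute_maf",
    "standardize",
    "filter_rare",
    "burden_score",
]


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes for one genomic region.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample identifiers (length q).
    G : ndarray, shape (q, n)
        Minor-allele counts in {0, 1, 2}; ``nan`` marks missing calls.
    variant_ids : list of str
    maf : ndarray, shape (n,)
        In-sample minor allele frequencies, in [0, 0.5].
    """

    samples: list
    G: np.ndarray
    variant_ids: list
    maf: np.ndarray = field(default=None)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise DimensionError("G must be 2-D (samples x variants)")
        if len(self.samples) != self.G.shape[0]:
            raise DimensionError("sample count does not match genotype rows")
        if len(self.variant_ids) != self.G.shape[1]:
            raise DimensionError("variant id count does not match genotype columns")
        if len(set(self.samples)) != len(self.samples):
            raise FamvcError("sample identifiers are not unique")
        obs = self.G[~np.isnan(self.G)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise FamvcError("genotypes must be coded 0/1/2 (nan for missing)")
        if self.maf is None:
            self.maf = compute_maf(self)
        else:
            self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_samples(self):
        return self.G.shape[0]

    @property
    def n_variants(self):
        return self.G.shape[1]

    def select_variants(self, mask):
        mask = np.asarray(mask)
        ids = [v for v, keep in zip(self.variant_ids, mask) if keep] \
            if mask.dtype == bool else [self.variant_ids[i] for i in mask]
        return GenotypeMatrix(self.samples, self.G[:, mask], ids, self.maf[mask])


@dataclass
class StandardizedGenotypes:
    """Column-standardized genotypes Z with z = (s − 2f)/sqrt(2f(1−f))."""

    samples: list
    Z: np.ndarray
    variant_ids: list
    freqs: np.ndarray

    @property
    def n_variants(self):
        return self.Z.shape[1]


def compute_maf(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """In-sample minor allele frequency per variant, folded to ≤ 0.5.

    f_j = (sum of non-missing counts) / (2 × non-missing sample count),
    folded to min(f, 1−f).  Raises on an all-missing column.
    """
    M = G.G if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)
    obs = ~np.isnan(M)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmax(n_obs == 0))
        name = G.variant_ids[j] if isinstance(G, GenotypeMatrix) else str(j)
        raise FamvcError(f"variant {name!r} has no non-missing genotypes")
    f = np.nansum(M, axis=0) / (2.0 * n_obs)
    return np.minimum(f, 1.0 - f)


def standardize(G: GenotypeMatrix, freqs=None, missing_policy="mean_impute") -> StandardizedGenotypes:
    """Standardize genotype columns; mean-impute missing entries (z = 0).

    ``freqs`` are the frequencies of the *counted* allele (defaults to the
    in-sample minor allele frequency).  Monomorphic columns (f ∈ {0, 1}) are
    dropped with a warning.
    """
    if missing_policy != "mean_impute":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    if freqs is None:
        obs = ~np.isnan(G.G)
        freqs = np.nansum(G.G, axis=0) / (2.0 * obs.sum(axis=0))
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] != G.n_variants:
        raise DimensionError("frequency vector length does not match variant count")
    poly = (freqs > 0.0) & (freqs < 1.0)
    if not np.all(poly):
        logger.warning("dropping %d monomorphic variants before standardization",
                       int((~poly).sum()))
    if not np.any(poly):
        raise EmptyRegionError("no polymorphic variants to standardize")
    f = freqs[poly]
    S = G.G[:, poly]
    n_missing = int(np.isnan(S).sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotype entries", n_missing)
    Z = (S - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    Z = np.nan_to_num(Z, nan=0.0)
    ids = [v for v, keep in zip(G.variant_ids, poly) if keep]
    return StandardizedGenotypes(G.samples, Z, ids, f)


def filter_rare(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep variants with in-sample MAF strictly below ``threshold``."""
    if not 0.0 < threshold <= 0.5:
        raise ValueError("threshold must be in (0, 0.5]")
    keep = G.maf < threshold
    if not np.any(keep):
        raise EmptyRegionError(f"no variant has MAF < {threshold}")
    return G.select_variants(keep)


def burden_score(G: GenotypeMatrix, standardized: bool = False) -> np.ndarray:
    """Per-individual sum of minor-allele counts (or standardized scores)."""
    if standardized:
        return standardize(G).Z.sum(axis=1)
    return np.nansum(G.G, axis=1)


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format=None) -> GenotypeMatrix:
    """Read genotypes from VCF, PLINK .raw text, or a CSV matrix.

    The format is inferred from the extension when not given.  Biallelic
    records only; multiallelic VCF rows are skipped with a warning.  Columns
    are oriented so the counted allele is the minor one in-sample.
    """
    if not os.path.exists(path):
        raise IOError(f"genotype file not found: {path}")
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = {".vcf": "vcf", ".gz": "vcf", ".raw": "plink_text",
                  ".csv": "matrix_csv"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer genotype format from {path!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_raw(path)
    if format == "matrix_csv":
        return _read_matrix_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _orient_minor(samples, G, ids):
    G = np.asarray(G, dtype=float)
    if G.shape[1] == 0:
        raise EmptyRegionError("no usable biallelic variants in input")
    obs = ~np.isnan(G)
    f = np.nansum(G, axis=0) / (2.0 * obs.sum(axis=0))
    flip = f > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    return GenotypeMatrix(list(samples), G, list(ids))


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = np.array(var.genotypes, dtype=object)
        counts = np.empty(len(samples))
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a is not None and a >= 0]
            counts[i] = np.nan if len(alleles) < 2 else float(sum(alleles))
        cols.append(counts)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
    if n_skipped:
        logger.warning("skipped %d non-biallelic VCF records", n_skipped)
    if not cols:
        raise EmptyRegionError("VCF contains no usable biallelic records")
    return _orient_minor(samples, np.column_stack(cols), ids)


def _read_plink_raw(path):
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in df.columns:
        raise IOError("PLINK .raw file lacks an IID column")
    geno = df.drop(columns=meta)
    return _orient_minor(df["IID"].astype(str).tolist(),
                         geno.to_numpy(dtype=float), list(geno.columns))


def _read_matrix_csv(path):
    df = pd.read_csv(path, index_col=0)
    return _orient_minor([str(s) for s in df.index],
                         df.to_numpy(dtype=float), list(df.columns))
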