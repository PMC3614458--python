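"""Simulation framework: haplotype pools, cohorts and phenotypes.

The generator reproduces the study conditions used to characterise the
region score test:

1. a neutral-coalescent pool of 10,000 haplotypes over a 500 kb region
   (effective population size 10⁴, mutation rate 1.5×10⁻⁸ per bp per
   generation, recombination rate varying over 100 kb windows), simulated
   with msprime;
2. a collapsing risk model — causal variants are drawn from the MAF < 2%
   sites of a randomly placed 500-variant window until the accumulated
   frequency of *risk haplotypes* (haplotypes carrying a minor allele at any
   causal site) reaches a target (10% by default);
3. cohorts mixing nuclear families (children ~ Poisson(2)) and unrelated
   individuals, founders drawing haplotype pairs from the pool with
   replacement and children inheriting one haplotype from each parent;
4. phenotypes y = g + p + e with g = u·z (z = risk-haplotype count),
   var(g) = 2r(1−r)u² = h², polygenic p (parent-averaged within families)
   and residual e chosen so var(g) + var(p) = 0.4 and var(e) = 0.6.

All randomness flows from explicit seeds; per-component substreams are
spawned from a master seed in :func:`run_study`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import FamvcError
from .genotype_io import GenotypeMatrix
from .relatedness import Pedigree, RelatednessSet, kinship_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePool",
    "SimulatedCohort",
    "simulate_pool",
    "assign_risk",
    "enrich_pool",
    "sample_cohort",
    "simulate_phenotypes",
    "draw_polygenic_trait",
    "run_study",
]


# ---------------------------------------------------------------------------
# haplotype pool


@dataclass
class HaplotypePool:
    """Binary haplotypes over segregating sites, plus the risk assignment.

    ``haplotypes`` is (n_hap, n_sites) with derived-allele indicators;
    ``region_sites`` indexes the tested window once :func:`assign_risk` has
    run, ``causal_sites`` the causal subset, and ``risk_flags`` marks
    haplotypes carrying a minor allele at any causal site.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    site_freqs: np.ndarray = None  # derived-allele frequencies
    region_sites: np.ndarray = None
    causal_sites: np.ndarray = None
    risk_flags: np.ndarray = None

    def __post_init__(self):
        if self.site_freqs is None:
            self.site_freqs = self.haplotypes.mean(axis=0)

    @property
    def n_haplotypes(self):
        return self.haplotypes.shape[0]

    @property
    def n_sites(self):
        return self.haplotypes.shape[1]

    @property
    def maf(self):
        return np.minimum(self.site_freqs, 1.0 - self.site_freqs)

    @property
    def risk_freq(self):
        return float(self.risk_flags.mean()) if self.risk_flags is not None else 0.0

    def minor_carrier(self, sites):
        """Boolean (n_hap, len(sites)): carries the minor allele at each site."""
        H = self.haplotypes[:, sites]
        minor_is_derived = self.site_freqs[sites] <= 0.5
        return np.where(minor_is_derived, H == 1, H == 0)


def simulate_pool(n_hap=10_000, length_bp=500_000, Ne=10_000, mu=1.5e-8,
                  recomb=None, seed=None, window_bp=100_000) -> HaplotypePool:
    """Neutral coalescent haplotype pool (msprime backend).

    ``recomb`` may be a scalar rate, a per-window rate array, or None for a
    seed-derived piecewise-constant profile over ``window_bp`` windows with
    mean 10⁻⁸ per bp per generation.  Monomorphic sites are dropped.
    """
    import msprime

    if min(n_hap, length_bp, Ne) <= 0 or mu < 0:
        raise ValueError("pool parameters must be positive")
    rng = np.random.default_rng(seed)
    n_windows = max(1, int(np.ceil(length_bp / window_bp)))
    edges = np.minimum(np.arange(n_windows + 1) * window_bp, length_bp).astype(float)
    if recomb is None:
        factors = rng.lognormal(mean=0.0, sigma=0.7, size=n_windows)
        rates = 1e-8 * factors / factors.mean()
    elif np.isscalar(recomb):
        rates = np.full(n_windows, float(recomb))
    else:
        rates = np.asarray(recomb, dtype=float)
        if rates.shape[0] != n_windows:
            raise ValueError("recombination profile length does not match windows")
    rate_map = msprime.RateMap(position=edges, rate=rates)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    if n_hap % 2:
        raise ValueError("n_hap must be even (haplotypes come in diploid pairs)")
    # diploid samples give the standard theta = 4 Ne mu scaling
    ts = msprime.sim_ancestry(samples=n_hap // 2, ploidy=2, population_size=Ne,
                              recombination_rate=rate_map,
                              random_seed=int(anc_seed))
    if mu > 0:
        ts = msprime.sim_mutations(ts, rate=mu, random_seed=int(mut_seed),
                                   model=msprime.BinaryMutationModel())
    H = ts.genotype_matrix().T.astype(np.uint8)  # (n_hap, n_sites)
    freqs = H.mean(axis=0)
    poly = (freqs > 0) & (freqs < 1)
    positions = np.array([s.position for s in ts.sites()])[poly]
    return HaplotypePool(haplotypes=np.ascontiguousarray(H[:, poly]),
                         positions=positions)


def assign_risk(pool: HaplotypePool, causal_maf_max=0.02, target_risk_freq=0.10,
                region_n_sites=500, correlated_pairs=False, seed=None) -> HaplotypePool:
    """Pick a region window and draw causal sites until the risk target is hit.

    Causal candidates are region sites with 0 < MAF < ``causal_maf_max``;
    sites are drawn in random order (adjacent pairs together when
    ``correlated_pairs``) and a haplotype becomes a risk haplotype as soon as
    it carries a minor allele at any drawn site.  Drawing stops when the
    risk-haplotype frequency reaches ``target_risk_freq``.
    """
    if causal_maf_max <= 0:
        raise ValueError("causal_maf_max must be positive")
    if pool.n_sites < region_n_sites:
        raise FamvcError("pool has fewer sites than the requested region")
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, pool.n_sites - region_n_sites + 1))
    region = np.arange(start, start + region_n_sites)
    maf = pool.maf[region]
    candidates = region[(maf > 0) & (maf < causal_maf_max)]
    if candidates.size == 0:
        raise FamvcError(f"region has no site with MAF < {causal_maf_max}")
    order = rng.permutation(candidates.size)
    if correlated_pairs:
        # draw nearby pairs: sort candidates, walk adjacent pairs in random order
        srt = np.sort(candidates)
        pairs = [srt[i:i + 2] for i in range(0, srt.size - 1, 2)]
        rng.shuffle(pairs)
        drawn_order = [s for p in pairs for s in p]
    else:
        drawn_order = candidates[order]
    carrier = pool.minor_carrier(np.asarray(drawn_order))
    risk = np.zeros(pool.n_haplotypes, dtype=bool)
    causal = []
    for k, site in enumerate(drawn_order):
        risk |= carrier[:, k]
        causal.append(site)
        if risk.mean() >= target_risk_freq:
            break
    else:
        raise FamvcError("risk-haplotype target unreachable with available "
                         f"causal candidates (reached {risk.mean():.3f})")
    return replace(pool, region_sites=region, causal_sites=np.sort(np.array(causal)),
                   risk_flags=risk)


def enrich_pool(pool: HaplotypePool, remove_nonrisk=2000, seed=None) -> HaplotypePool:
    """Ascertainment surrogate: delete non-risk haplotypes uniformly at random."""
    if pool.risk_flags is None:
        raise FamvcError("assign_risk must run before enrich_pool")
    if remove_nonrisk == 0:
        return pool
    nonrisk = np.flatnonzero(~pool.risk_flags)
    if nonrisk.size < remove_nonrisk:
        raise FamvcError("not enough non-risk haplotypes to remove")
    rng = np.random.default_rng(seed)
    drop = rng.choice(nonrisk, size=remove_nonrisk, replace=False)
    keep = np.setdiff1d(np.arange(pool.n_haplotypes), drop)
    return replace(pool, haplotypes=pool.haplotypes[keep],
                   site_freqs=pool.site_freqs,  # keep pool-level frequencies
                   risk_flags=pool.risk_flags[keep])


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SimulatedCohort:
    """Genotypes, pedigree and (once simulated) phenotypes for one replicate."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    unrelated_ids: list
    risk_counts: np.ndarray
    haplotype_pairs: np.ndarray  # (q, 2, region_n_sites) minor-allele indicators
    is_child: np.ndarray
    parent_index: np.ndarray  # (q, 2) indices into samples, -1 for founders
    phenotypes: np.ndarray = None
    true_components: dict = None

    @property
    def samples(self):
        return self.genotypes.samples

    def relatedness(self, household=False) -> RelatednessSet:
        """Kinship-based background structure 2Φ (and C) in this sample order."""
        samples, A = kinship_matrix(self.pedigree, self.unrelated_ids)
        if samples != self.samples:
            raise FamvcError("kinship order does not match cohort order")
        C = None
        if household:
            from .relatedness import household_matrix
            _, C = household_matrix(self.pedigree, self.unrelated_ids)
        return RelatednessSet(samples, A, C)


def sample_cohort(pool: HaplotypePool, n_families, n_unrelated,
                  children_lambda=2.0, seed=None,
                  founder_pool: HaplotypePool = None) -> SimulatedCohort:
    """Draw a cohort of nuclear families plus unrelated individuals.

    Founders and unrelated individuals receive two haplotypes sampled with
    replacement (founders from ``founder_pool`` when given — the enriched
    design); each child inherits one uniformly chosen haplotype from each
    parent.  Haplotypes are collapsed to unphased genotypes over the region.
    """
    if pool.region_sites is None or pool.risk_flags is None:
        raise FamvcError("assign_risk must run before sampling a cohort")
    fpool = founder_pool if founder_pool is not None else pool
    rng = np.random.default_rng(seed)
    region = pool.region_sites
    Hpool = pool.minor_carrier(region)          # minor-allele indicators
    Hfound = fpool.minor_carrier(region) if founder_pool is not None else Hpool

    sample_ids, ped_rows = [], []
    hap_idx = []      # (source, hap_row) pairs
    parent_index, is_child = [], []

    def draw_pair(source_H, src):
        i, j = rng.integers(0, source_H.shape[0], size=2)
        return (src, int(i)), (src, int(j))

    for f in range(n_families):
        fid = f"F{f}"
        n_children = int(rng.poisson(children_lambda))
        pa, ma = f"{fid}_p1", f"{fid}_p2"
        idx_pa = len(sample_ids)
        sample_ids.append(pa)
        ped_rows.append((fid, pa, None, None))
        hap_idx.append(draw_pair(Hfound, "f"))
        parent_index.append((-1, -1)); is_child.append(False)
        idx_ma = len(sample_ids)
        sample_ids.append(ma)
        ped_rows.append((fid, ma, None, None))
        hap_idx.append(draw_pair(Hfound, "f"))
        parent_index.append((-1, -1)); is_child.append(False)
        for c in range(n_children):
            cid = f"{fid}_c{c + 1}"
            sample_ids.append(cid)
            ped_rows.append((fid, cid, pa, ma))
            from_pa = hap_idx[idx_pa][int(rng.integers(2))]
            from_ma = hap_idx[idx_ma][int(rng.integers(2))]
            hap_idx.append((from_pa, from_ma))
            parent_index.append((idx_pa, idx_ma)); is_child.append(True)
    unrelated_ids = [f"U{i}" for i in range(n_unrelated)]
    for uid in unrelated_ids:
        sample_ids.append(uid)
        hap_idx.append(draw_pair(Hpool, "p"))
        parent_index.append((-1, -1)); is_child.append(False)

    q = len(sample_ids)
    rows = np.array([[h[0][1], h[1][1]] for h in hap_idx], dtype=int)
    from_f = np.array([[h[0][0] == "f", h[1][0] == "f"] for h in hap_idx])
    rows_f = np.where(from_f, rows, 0)  # pools may differ in size
    rows_p = np.where(from_f, 0, rows)
    hap_pairs = np.where(from_f[:, :, None], Hfound[rows_f], Hpool[rows_p]) \
        .astype(np.uint8)
    risk_of = np.where(from_f, fpool.risk_flags[rows_f], pool.risk_flags[rows_p])
    risk_counts = risk_of.sum(axis=1).astype(np.int8)

    G = hap_pairs.sum(axis=1).astype(float)
    # orient to the in-sample minor allele
    f_in = G.sum(axis=0) / (2.0 * q)
    flip = f_in > 0.5
    G[:, flip] = 2.0 - G[:, flip]
    ids = [f"site{j}" for j in region]
    geno = GenotypeMatrix(sample_ids, G, ids)
    if ped_rows:
        ped = Pedigree.from_tuples(ped_rows)
    else:
        ped = Pedigree(pd.DataFrame(columns=["fid", "iid", "father", "mother"],
                                    dtype=str))
    return SimulatedCohort(genotypes=geno, pedigree=ped,
                           unrelated_ids=unrelated_ids,
                           risk_counts=risk_counts,
                           haplotype_pairs=hap_pairs,
                           is_child=np.array(is_child),
                           parent_index=np.array(parent_index, dtype=int))


def simulate_phenotypes(cohort: SimulatedCohort, h2, pool_risk_freq,
                        total_genetic=0.4, u=None, seed=None,
                        child_mode="faithful") -> SimulatedCohort:
    """Phenotypes y = g + p + e (centered) under the collapsing risk model.

    var(g) = 2r(1−r)u² equals ``h2`` on the unit total-variance scale; the
    residual variance splits into a polygenic part var(p) = total_genetic −
    var(g) and noise var(e) = 1 − total_genetic.  Children's polygenic values
    are p_c = ½(p_m + p_f) + ½ p_i with p_i ~ N(0, var(p)) (``faithful``;
    var(p_c) = ¾ var(p)), or p_c = ½(p_m + p_f) + sqrt(½) p_i
    (``variance_preserving``).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    r = float(pool_risk_freq)
    var_g = h2
    if var_g > total_genetic:
        raise ValueError("h2 implies var(g) > total genetic variance; split impossible")
    if u is None:
        u = 0.0 if h2 == 0 else float(np.sqrt(h2 / (2.0 * r * (1.0 - r))))
    var_p = total_genetic - var_g
    var_e = 1.0 - total_genetic
    rng = np.random.default_rng(seed)
    q = len(cohort.samples)
    g = u * cohort.risk_counts.astype(float)
    p = np.empty(q)
    founders = ~cohort.is_child
    p[founders] = rng.normal(0.0, np.sqrt(var_p), size=int(founders.sum()))
    # children in record order always follow their parents
    child_rows = np.flatnonzero(cohort.is_child)
    pi = rng.normal(0.0, np.sqrt(var_p), size=child_rows.size)
    coef = 0.5 if child_mode == "faithful" else np.sqrt(0.5)
    if child_mode not in ("faithful", "variance_preserving"):
        raise ValueError(f"unknown child_mode {child_mode!r}")
    for k, row in enumerate(child_rows):
        pa, ma = cohort.parent_index[row]
        p[row] = 0.5 * (p[pa] + p[ma]) + coef * pi[k]
    e = rng.normal(0.0, np.sqrt(var_e), size=q)
    y = g + p + e
    y = y - y.mean()
    return replace(cohort, phenotypes=y,
                   true_components={"g": g, "p": p, "e": e, "u": u,
                                    "var_g": var_g, "var_p": var_p,
                                    "var_e": var_e})


def draw_polygenic_trait(rel: RelatednessSet, sigma2_delta, sigma2_eps, seed=None):
    """Exact multivariate-normal draw y ~ N(0, σδ²A + σε²I) (for calibration)."""
    rng = np.random.default_rng(seed)
    q = len(rel.samples)
    V = rel.A.combine([sigma2_delta], [rel.A], diag=sigma2_eps) \
        if not hasattr(rel.A, "M") else None
    z = rng.standard_normal(q)
    if V is not None:
        out = np.empty(q)
        for idx, dat in V.groups:
            m, s = idx.shape
            L = np.linalg.cholesky(dat)
            out[idx.ravel()] = np.matmul(L, z[idx.ravel()].reshape(m, s, 1)).ravel()
        return out
    Vd = sigma2_delta * rel.A.to_dense() + sigma2_eps * np.eye(q)
    return np.linalg.cholesky(Vd) @ z


# ---------------------------------------------------------------------------
# study driver


DESIGN_PRESETS = {
    "primary": dict(n_families=500, n_unrelated=2000, enriched=False),
    "I": dict(n_families=500, n_unrelated=3000, enriched=False),
    "II": dict(n_families=750, n_unrelated=2000, enriched=False),
    "III": dict(n_families=750, n_unrelated=2000, enriched=True),
}


def run_study(pool: HaplotypePool = None, design="primary", h2_grid=(0.0, 0.01),
              alpha_levels=(0.05, 1e-5), n_reps=200, methods=("davies",
              "satterthwaite_gamma"), seed=0, n_families=None, n_unrelated=None,
              enriched=None, target_risk_freq=0.10, children_lambda=2.0,
              remove_nonrisk=2000, fgls=False, collect_pvalues=False):
    """Replicated type-I-error / power study for one design.

    Per replicate the risk assignment, cohort and phenotypes are all redrawn
    (the haplotype pool is fixed); the score test runs on the 500-variant
    region with kinship-based A under REML.  Returns a tidy DataFrame of
    rejection rates per (h2, alpha, method) with Monte Carlo standard
    errors; with ``collect_pvalues`` the per-replicate p-values come along
    in ``df.attrs['pvalues']``.
    """
    from .fgls import fgls_test
    from .genotype_io import burden_score
    from .kernels import linear_similarity, burden_similarity
    from .genotype_io import standardize
    from .null_model import fit_null
    from .score_test import test_region

    preset = DESIGN_PRESETS.get(design, {})
    n_families = preset.get("n_families") if n_families is None else n_families
    n_unrelated = preset.get("n_unrelated") if n_unrelated is None else n_unrelated
    enriched = preset.get("enriched", False) if enriched is None else enriched
    master = np.random.SeedSequence(seed)
    if pool is None:
        pool_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        pool = simulate_pool(seed=pool_seed)

    rows = []
    pvals_store = {}
    for h2 in h2_grid:
        rep_seeds = master.spawn(n_reps)
        pv = {m: np.empty(n_reps) for m in methods}
        if fgls:
            pv["fgls"] = np.empty(n_reps)
        for rep in range(n_reps):
            ss = rep_seeds[rep]
            s_risk, s_enrich, s_cohort, s_pheno = (
                int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4))
            rp = assign_risk(pool, target_risk_freq=target_risk_freq, seed=s_risk)
            founder_pool = enrich_pool(rp, remove_nonrisk, seed=s_enrich) \
                if enriched else None
            cohort = sample_cohort(rp, n_families, n_unrelated,
                                   children_lambda=children_lambda,
                                   seed=s_cohort, founder_pool=founder_pool)
            cohort = simulate_phenotypes(cohort, h2, rp.risk_freq, seed=s_pheno)
            rel = cohort.relatedness()
            fit = fit_null(cohort.phenotypes, rel=rel, method="reml")
            S = linear_similarity(standardize(cohort.genotypes))
            res = test_region(cohort.phenotypes, rel=rel, similarity=S,
                              null_fit=fit, p_methods=methods)
            for m in methods:
                pv[m][rep] = res.p_values[m]
            if fgls:
                b = burden_score(cohort.genotypes, standardized=True)
                pv["fgls"][rep] = fgls_test(None, None, b, fit).p
        for m, arr in pv.items():
            for alpha in alpha_levels:
                power = float(np.mean(arr < alpha))
                rows.append(dict(design=design, h2=h2, alpha=alpha, method=m,
                                 power=power, n_reps=n_reps,
                                 mc_se=float(np.sqrt(power * (1 - power)
                                                     / n_reps))))
        pvals_store[h2] = {m: arr.copy() for m, arr in pv.items()}
    df = pd.DataFrame(rows)
    if collect_pvalues:
        df.attrs["pvalues"] = pvals_store
    return df
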