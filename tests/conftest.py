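"""Shared fixtures: small pedigrees, cohorts and a session-scoped haplotype pool."""

import numpy as np
import pytest

from famvc.relatedness import Pedigree, RelatednessSet, kinship_matrix
from famvc.simulate import assign_risk, simulate_pool


def nuclear_families(n_fam, n_children=2):
    rows = []
    for f in range(n_fam):
        fid = f"F{f}"
        rows += [(fid, f"{fid}_p1", None, None), (fid, f"{fid}_p2", None, None)]
        rows += [(fid, f"{fid}_c{k+1}", f"{fid}_p1", f"{fid}_p2")
                 for k in range(n_children)]
    return Pedigree.from_tuples(rows)


@pytest.fixture
def small_pedigree():
    return nuclear_families(5)


@pytest.fixture
def mixed_relatedness():
    """20 nuclear families (2 kids) + 40 unrelated individuals."""
    ped = nuclear_families(20)
    unrelated = [f"U{i}" for i in range(40)]
    samples, A = kinship_matrix(ped, unrelated)
    return ped, unrelated, RelatednessSet(samples, A)


@pytest.fixture(scope="session")
def small_pool():
    """Reduced coalescent pool (2,000 haplotypes, 100 kb) with risk assigned."""
    pool = simulate_pool(n_hap=2000, length_bp=100_000, seed=99)
    return assign_risk(pool, region_n_sites=min(500, pool.n_sites), seed=17)


def draw_mvn(rel, s2d, s2e, rng):
    """y ~ N(0, s2d*A + s2e*I) via dense Cholesky (oracle path for tests)."""
    A = rel.A.to_dense()
    q = A.shape[0]
    L = np.linalg.cholesky(s2d * A + s2e * np.eye(q))
    return L @ rng.standard_normal(q)
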