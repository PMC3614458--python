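"""Haplotype pool, risk model, cohort transmission and phenotype bookkeeping."""

import numpy as np
import pytest

from famvc.exceptions import FamvcError
from famvc.simulate import (assign_risk, enrich_pool, run_study, sample_cohort,
                            simulate_phenotypes, simulate_pool)


class TestPool:
    def test_watterson_segregating_sites(self):
        # E[S] = theta * a_{n-1}, theta = 4 Ne mu L; desk-scale pool
        n_hap, L, Ne, mu = 2000, 100_000, 10_000, 1.5e-8
        theta = 4 * Ne * mu * L
        a_n = np.sum(1.0 / np.arange(1, n_hap))
        expected = theta * a_n
        counts = [simulate_pool(n_hap, L, Ne, mu, seed=s).n_sites
                  for s in (1, 2, 3)]
        # sd of S is below sqrt(E[S]) + theta-linked term; use a generous band
        assert abs(np.mean(counts) - expected) < 4 * np.sqrt(expected) + 0.1 * expected

    def test_zero_mutation_rate_no_sites(self):
        pool = simulate_pool(n_hap=100, length_bp=10_000, mu=0.0, seed=1)
        assert pool.n_sites == 0

    def test_rare_fraction_near_neutral_expectation(self, small_pool):
        # neutral folded SFS: P(maf < 0.05) ~ 0.7
        frac = np.mean(small_pool.maf < 0.05)
        assert 0.6 < frac < 0.8

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_pool(n_hap=0)
        with pytest.raises(ValueError):
            simulate_pool(n_hap=999)  # odd


class TestRisk:
    def test_stopping_rule_brackets_target(self, small_pool):
        inc = 1.0 / small_pool.n_haplotypes
        # realized frequency >= target; overshoot bounded by the largest
        # single-site carrier mass among causal candidates
        assert small_pool.risk_freq >= 0.10
        assert small_pool.risk_freq <= 0.10 + 0.02 + inc

    def test_flags_match_collapsing_rule(self, small_pool):
        carrier = small_pool.minor_carrier(small_pool.causal_sites)
        np.testing.assert_array_equal(small_pool.risk_flags,
                                      carrier.any(axis=1))

    def test_zero_maf_threshold_errors(self, small_pool):
        with pytest.raises(ValueError):
            assign_risk(small_pool, causal_maf_max=0.0, seed=1)

    def test_deterministic_under_seed(self, small_pool):
        r1 = assign_risk(small_pool, seed=5)
        r2 = assign_risk(small_pool, seed=5)
        np.testing.assert_array_equal(r1.causal_sites, r2.causal_sites)
        np.testing.assert_array_equal(r1.risk_flags, r2.risk_flags)


class TestEnrich:
    def test_exact_arithmetic(self, small_pool):
        n_risk = int(small_pool.risk_flags.sum())
        enriched = enrich_pool(small_pool, remove_nonrisk=500, seed=2)
        assert enriched.n_haplotypes == small_pool.n_haplotypes - 500
        assert int(enriched.risk_flags.sum()) == n_risk
        expected = n_risk / (small_pool.n_haplotypes - 500)
        assert enriched.risk_flags.mean() == pytest.approx(expected)

    def test_zero_removal_is_identity(self, small_pool):
        assert enrich_pool(small_pool, 0) is small_pool

    def test_insufficient_nonrisk_errors(self, small_pool):
        with pytest.raises(FamvcError):
            enrich_pool(small_pool, remove_nonrisk=small_pool.n_haplotypes)


class TestCohort:
    def test_mendelian_transmission(self, small_pool):
        cohort = sample_cohort(small_pool, 30, 10, seed=3)
        for row in np.flatnonzero(cohort.is_child):
            pa, ma = cohort.parent_index[row]
            h0, h1 = cohort.haplotype_pairs[row]
            assert any((h0 == cohort.haplotype_pairs[pa][a]).all()
                       for a in range(2))
            assert any((h1 == cohort.haplotype_pairs[ma][a]).all()
                       for a in range(2))

    def test_poisson_children_mean(self, small_pool):
        rng_reps = 400
        cohort = sample_cohort(small_pool, rng_reps, 0, seed=4)
        n_children = int(cohort.is_child.sum())
        mean = n_children / rng_reps
        assert abs(mean - 2.0) < 3 * np.sqrt(2.0 / rng_reps)

    def test_unrelated_only_cohort(self, small_pool):
        cohort = sample_cohort(small_pool, 0, 25, seed=5)
        assert len(cohort.samples) == 25
        assert not cohort.is_child.any()
        rel = cohort.relatedness()
        np.testing.assert_array_equal(rel.A.to_dense(), np.eye(25))

    def test_risk_counts_consistent_with_haplotypes(self, small_pool):
        cohort = sample_cohort(small_pool, 20, 20, seed=6)
        causal_local = np.searchsorted(small_pool.region_sites,
                                       small_pool.causal_sites)
        carried = cohort.haplotype_pairs[:, :, causal_local].any(axis=2)
        np.testing.assert_array_equal(carried.sum(axis=1), cohort.risk_counts)

    def test_transmission_preserves_frequencies(self, small_pool):
        cohort = sample_cohort(small_pool, 500, 0, seed=7)
        pool_freq = small_pool.minor_carrier(small_pool.region_sites).mean(axis=0)
        sample_freq = cohort.haplotype_pairs.mean(axis=(0, 1))
        # expectation equality, MC error ~ 1/sqrt(2q)
        assert np.abs(sample_freq - pool_freq).mean() < 0.01


class TestPhenotypes:
    def test_null_configuration_variances(self, small_pool):
        cohort = sample_cohort(small_pool, 0, 8000, seed=8)
        cohort = simulate_phenotypes(cohort, 0.0, small_pool.risk_freq, seed=9)
        tc = cohort.true_components
        assert tc["u"] == 0.0
        assert tc["var_p"] == pytest.approx(0.4)
        assert tc["var_e"] == pytest.approx(0.6)
        assert np.var(cohort.phenotypes) == pytest.approx(1.0, abs=0.05)

    def test_effect_size_closed_form(self, small_pool):
        cohort = sample_cohort(small_pool, 0, 50, seed=10)
        cohort = simulate_phenotypes(cohort, 0.02, 0.10, seed=11)
        assert cohort.true_components["u"] == pytest.approx(
            np.sqrt(0.02 / (2 * 0.1 * 0.9)))
        assert cohort.true_components["u"] == pytest.approx(0.3333, abs=1e-4)

    def test_unit_total_variance_bookkeeping(self, small_pool):
        cohort = sample_cohort(small_pool, 0, 10_000, seed=12)
        cohort = simulate_phenotypes(cohort, 0.01, small_pool.risk_freq, seed=13)
        # var(y) = var(g) + var(p) + var(e) = 1 for unrelateds
        assert np.var(cohort.phenotypes) == pytest.approx(1.0, abs=0.05)

    def test_decomposition_exact_and_centered(self, small_pool):
        cohort = sample_cohort(small_pool, 10, 10, seed=14)
        cohort = simulate_phenotypes(cohort, 0.01, small_pool.risk_freq, seed=15)
        tc = cohort.true_components
        y_raw = tc["g"] + tc["p"] + tc["e"]
        np.testing.assert_allclose(cohort.phenotypes, y_raw - y_raw.mean(),
                                   atol=1e-12)
        assert abs(cohort.phenotypes.mean()) < 1e-12

    def test_child_polygenic_variance_modes(self, small_pool):
        cohort = sample_cohort(small_pool, 3000, 0, seed=16)
        faithful = simulate_phenotypes(cohort, 0.0, 0.1, seed=17,
                                       child_mode="faithful")
        preserving = simulate_phenotypes(cohort, 0.0, 0.1, seed=17,
                                         child_mode="variance_preserving")
        kids = cohort.is_child
        var_f = faithful.true_components["p"][kids].var()
        var_p = preserving.true_components["p"][kids].var()
        assert var_f == pytest.approx(0.75 * 0.4, rel=0.1)
        assert var_p == pytest.approx(0.4, rel=0.1)

    def test_impossible_split_rejected(self, small_pool):
        cohort = sample_cohort(small_pool, 0, 10, seed=18)
        with pytest.raises(ValueError):
            simulate_phenotypes(cohort, 0.5, 0.1, seed=19)


class TestRunStudy:
    def test_seed_reproducibility_and_monotonicity(self, small_pool):
        kw = dict(pool=small_pool, design="custom", n_families=25,
                  n_unrelated=50, enriched=False, alpha_levels=(0.05,),
                  methods=("satterthwaite_gamma",), n_reps=8, seed=42)
        df1 = run_study(h2_grid=(0.0, 0.05), **kw)
        df2 = run_study(h2_grid=(0.0, 0.05), **kw)
        assert df1["power"].tolist() == df2["power"].tolist()
        assert {"design", "h2", "alpha", "method", "power", "n_reps",
                "mc_se"} <= set(df1.columns)

    def test_fgls_column_present_when_requested(self, small_pool):
        df = run_study(pool=small_pool, design="custom", n_families=10,
                       n_unrelated=20, enriched=False, h2_grid=(0.0,),
                       alpha_levels=(0.05,), methods=("satterthwaite_gamma",),
                       n_reps=3, seed=1, fgls=True)
        assert "fgls" in set(df["method"])
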