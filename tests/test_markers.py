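import numpy as np
import pytest

import wgblup
from oracles import gls_marker_fit
from wgblup.data import TraitTable, deregress
from wgblup.markers import (GibbsConfig, _gibbs_kernel, bl_gibbs,
                            bl_hyperparams, ms_w, prior_scales, rr_gibbs,
                            sm_scan)


class TestPriorCalibration:
    def test_ms_w_reference_values(self):
        class G:
            calls = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert ms_w(G.calls) == pytest.approx(2.0)
        assert ms_w(np.ones((5, 3))) == 0.0
        # duplicating every individual leaves the per-individual sum intact
        x = np.array([[0.0, 1.0], [2.0, 1.0], [1.0, 0.0]])
        assert ms_w(np.vstack([x, x])) == pytest.approx(ms_w(x))

    def test_prior_scales_reference_values(self):
        s_a, s_e, s_rr = prior_scales(1.0, 0.5, 5.0, 2.0)
        assert s_a == pytest.approx(0.75)
        assert s_e == pytest.approx(1.5)
        assert s_rr == pytest.approx(0.375)
        with pytest.raises(ValueError):
            prior_scales(1.0, 0.5, 2.0, 1.0)

    def test_small_h2_limit(self):
        s_a, _, _ = prior_scales(1.0, 1e-9, 5.0, 1.0)
        assert s_a < 1e-8

    def test_bl_hyperparams_reference_values(self):
        alpha2, lam = bl_hyperparams(0.5, 2.0, alpha1=1.01)
        assert alpha2 == pytest.approx(0.0025)
        assert lam == pytest.approx(2.0)
        # the gamma anchor reproduces the target: sqrt((a1-1)/a2) = lam
        assert np.sqrt((1.01 - 1) / alpha2) == pytest.approx(lam)


class TestSingleMarkerScan:
    def test_perfect_association_and_monomorphic(self, small_cohort):
        ped, g, trait, _ = small_cohort
        g2 = wgblup.GenotypeMatrix(g.individual_ids, g.calls.copy(), g.map)
        # marker 0: re-coded to track the phenotype; marker 1: monomorphic
        z = (trait.depta - trait.depta.mean()) / trait.depta.std()
        g2.calls[:, 0] = np.clip(np.round(z + 1), 0, 2)
        g2.calls[:, 1] = 1.0
        eff = sm_scan(trait, g2, ped)
        assert eff.p_value[0] < 1e-6
        assert eff.indicator[0] == 1
        assert eff.p_value[1] == 1.0
        assert eff.indicator[1] == 0

    def test_reduces_to_weighted_least_squares_without_sire_variance(
            self, small_cohort):
        ped, g, trait, _ = small_cohort
        eff = sm_scan(trait, g, ped, sire_h2=0.0)
        v_y = float(np.var(trait.depta))
        V = np.diag(v_y / trait.record_weight)
        for j in range(0, 20):
            b, f = gls_marker_fit(trait.depta, g.calls[:, j], V)
            assert eff.effect[j] == pytest.approx(b, rel=1e-8)

    def test_indicator_threshold_is_strict(self, small_cohort):
        ped, g, trait, _ = small_cohort
        eff = sm_scan(trait, g, ped, alpha=0.05)
        assert np.array_equal(eff.indicator == 1, eff.p_value < 0.05)
        at_boundary = sm_scan(trait, g, ped,
                              alpha=float(eff.p_value.min()))
        j = int(np.argmin(eff.p_value))
        assert at_boundary.indicator[j] == 0  # p == alpha -> not selected


class TestGibbsSamplers:
    def test_deterministic_under_seed(self, small_cohort):
        ped, g, trait, _ = small_cohort
        cfg = GibbsConfig(n_iter=400, burn_in=100, thin=2, seed=5)
        e1, s1 = rr_gibbs(trait, g, ped, cfg)
        e2, s2 = rr_gibbs(trait, g, ped, cfg)
        np.testing.assert_array_equal(e1.effect, e2.effect)
        assert s1.posterior_mean == s2.posterior_mean
        b1, _ = bl_gibbs(trait, g, ped, cfg)
        b2, _ = bl_gibbs(trait, g, ped, cfg)
        np.testing.assert_array_equal(b1.effect, b2.effect)

    def test_null_phenotype_gives_null_effects(self, small_cohort):
        ped, g, trait, _ = small_cohort
        t0 = TraitTable(trait.ids, np.zeros(len(trait)), trait.reliability,
                        trait.h2, depta=np.zeros(len(trait)),
                        record_weight=trait.record_weight)
        cfg = GibbsConfig(n_iter=2000, burn_in=500, thin=5, seed=6)
        eff, _ = rr_gibbs(t0, g, ped, cfg)
        mcse = eff.posterior_sd / np.sqrt(300)
        assert np.all(np.abs(eff.effect) < 3e-3 + 3 * mcse)

    def test_rr_matches_ridge_closed_form_with_pinned_variances(self):
        """With the variance priors collapsed to point masses and the
        polygenic effect pinned at zero, the RR posterior mean must equal
        the ridge regression solution."""
        rng = np.random.default_rng(17)
        n, m = 80, 30
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        beta = rng.normal(0, 0.3, m)
        y = X @ beta + rng.normal(0, 1.0, n)
        w = np.ones(n)
        sigma_e, sigma_u = 1.0, 0.09
        nu = 1e8  # pins each variance at S/(nu-2)
        status, u_sum, u_sq, kept, _ = _gibbs_kernel(
            np.ascontiguousarray(X.T), y, w, np.eye(n),
            1e-12 * (nu - 2), sigma_e * (nu - 2), sigma_u * (nu - 2),
            nu, 40_000, 4_000, 4, 3, False, 1.01, 1.0, 0.0)
        assert status == 0
        u_hat = u_sum / kept
        lam = sigma_e / sigma_u
        C = np.zeros((m + 1, m + 1))
        C[0, 0] = n
        C[0, 1:] = X.sum(axis=0)
        C[1:, 0] = C[0, 1:]
        C[1:, 1:] = X.T @ X + lam * np.eye(m)
        sol = np.linalg.solve(C, np.concatenate(([y.sum()], X.T @ y)))
        scale = np.abs(sol[1:]).mean()
        assert np.max(np.abs(u_hat - sol[1:])) < 1e-2 * max(scale, 1.0)

    def test_bl_shrinkage_monotone_in_lambda(self, small_cohort):
        ped, g, trait, _ = small_cohort
        cfg = GibbsConfig(n_iter=2000, burn_in=500, thin=5, seed=8)
        means = []
        for lam2 in (1.0, 1e3, 1e6):
            eff, _ = bl_gibbs(trait, g, ped, cfg, lambda2_fixed=lam2)
            means.append(np.mean(np.abs(eff.effect)))
        assert means[0] > means[1] > means[2]

    def test_bl_concentrates_on_sparse_architecture(self):
        """On a sparse trait, BL should shrink null markers harder than RR
        relative to the QTL markers (smaller null-to-QTL ratio)."""
        wins = 0
        for seed in range(5):
            ped = wgblup.sim_pedigree(60, 6, 15, 2, seed=seed)
            g = wgblup.sim_genotypes(ped, 400, ld_rho=0.5,
                                     map_length_mb=80, seed=seed + 50,
                                     n_chromosomes=2)
            spec = wgblup.ArchitectureSpec(n_qtl=5, h2=0.6,
                                           major_fraction=0.4)
            trait, truth = wgblup.sim_trait(g, spec, seed=seed + 100)
            cfg = GibbsConfig(n_iter=3000, burn_in=500, thin=5, seed=seed)
            rr, _ = rr_gibbs(trait, g, ped, cfg)
            bl, _ = bl_gibbs(trait, g, ped, cfg)
            qtl = truth.qtl_indices
            null = np.setdiff1d(np.arange(g.n_markers), qtl)

            def ratio(e):
                return (np.mean(np.abs(e.effect[null]))
                        / np.mean(np.abs(e.effect[qtl])))

            wins += ratio(bl) < ratio(rr)
        assert wins >= 3

    def test_chain_summary_uses_kept_samples_only(self, small_cohort):
        ped, g, trait, _ = small_cohort
        cfg = GibbsConfig(n_iter=1000, burn_in=400, thin=3, seed=2)
        _, summ = rr_gibbs(trait, g, ped, cfg)
        assert summ.n_samples == 200
        assert set(summ.posterior_mean) == {"sigma2_u", "sigma2_a",
                                            "sigma2_e"}
        assert all(v > 0 for v in summ.posterior_mean.values())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GibbsConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            GibbsConfig(nu=2.0)
        with pytest.raises(ValueError):
            GibbsConfig(thin=0)
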