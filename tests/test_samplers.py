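"""MCMC samplers: reproducibility, calibration, and oracle agreement."""

import numpy as np
import pytest

from gsarch import genomatrix as gm
from gsarch import lmm, samplers
from gsarch.annotate import AnnotationMap
from gsarch.samplers import McmcConfig, MixtureSpec
from gsarch.simdata import SimConfig, simulate_genotypes

from conftest import make_geno

CFG = dict(n_iter=600, burn_in=200)


@pytest.fixture(scope="module")
def geno_mid():
    return simulate_genotypes(SimConfig(n_individuals=400, n_markers=800,
                                        seed=51))


@pytest.fixture(scope="module")
def qtl_sim(geno_mid):
    """20 causal markers out of 800, h2 = 0.5."""
    rng = np.random.default_rng(60)
    X = gm.design_matrix(geno_mid, "standardized")
    causal = rng.choice(geno_mid.n_markers, 20, replace=False)
    beta = np.zeros(geno_mid.n_markers)
    beta[causal] = rng.normal(0, 1, 20)
    g = X @ beta
    g = g / g.std()
    y = g + rng.normal(0, 1, geno_mid.n_samples)
    return y, causal, g


class TestReproducibilityAndInvariants:
    def test_seeded_chains_bit_identical(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        cfg = McmcConfig(seed=7, **CFG)
        a = samplers.run_bayes_r(y, geno_mid, cfg)
        b = samplers.run_bayes_r(y, geno_mid, cfg)
        np.testing.assert_array_equal(a.beta_mean, b.beta_mean)
        np.testing.assert_array_equal(a.traces["h2"], b.traces["h2"])

    def test_mixture_proportions_and_residuals(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=1, **CFG))
        np.testing.assert_allclose(post.pi_est.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(post.traces["sigma2_e"] > 0)
        assert np.all((post.pip >= 0) & (post.pip <= 1))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="burn_in"):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="increasing"):
            MixtureSpec(rel_variances=(1e-3, 1e-3))


class TestBayesCpi:
    def test_null_phenotype_calibration(self, geno_mid):
        """No genetic signal: posterior h2 small, few markers included."""
        h2s, pips = [], []
        for seed in range(3):
            y = np.random.default_rng(800 + seed).normal(size=geno_mid.n_samples)
            post = samplers.run_bayes_cpi(y, geno_mid,
                                          McmcConfig(seed=seed, **CFG))
            h2s.append(post.h2)
            pips.append(post.pip.mean())
        assert np.mean(h2s) < 0.1
        assert np.mean(pips) < 0.1

    def test_causal_markers_rank_higher(self, geno_mid, qtl_sim):
        y, causal, _ = qtl_sim
        diffs = []
        for seed in range(3):
            post = samplers.run_bayes_cpi(y, geno_mid,
                                          McmcConfig(seed=seed, **CFG))
            mask = np.zeros(geno_mid.n_markers, bool)
            mask[causal] = True
            diffs.append(post.pip[mask].mean() - post.pip[~mask].mean())
        assert all(d > 0 for d in diffs)

    def test_single_marker_conjugate_closed_form(self):
        """pi=0 with fixed variances reduces to ridge regression."""
        rng = np.random.default_rng(3)
        n = 300
        dos = (rng.random(n) < 0.4) * 1.0 + (rng.random(n) < 0.4)
        geno = make_geno(dos[:, None])
        x = gm.design_matrix(geno, "standardized").ravel()
        beta_true = 0.3
        y = x * beta_true + rng.normal(0, 0.5, n)
        s2b, s2e = 0.25, 0.25
        cfg = McmcConfig(n_iter=4000, burn_in=500, seed=4,
                         fix_sigma2_beta=s2b, fix_sigma2_e=s2e,
                         fix_pi_null=0.0, update_mu=False)
        post = samplers.run_bayes_cpi(y, geno, cfg)
        d = x @ x + s2e / s2b
        expected_mean = x @ y / d
        mc_se = np.sqrt(s2e / d) / np.sqrt(post.traces["h2"][500:].size)
        assert post.beta_mean[0] == pytest.approx(expected_mean,
                                                  abs=6 * mc_se)
        assert post.pip[0] == 1.0


class TestBayesRFamily:
    def test_null_phenotype_few_large_effects(self, geno_mid):
        """Without signal the large-effect component stays nearly empty."""
        y = np.random.default_rng(90).normal(size=geno_mid.n_samples)
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=2, **CFG))
        large = post.traces["component_counts"][200:, -1]
        assert large.mean() / geno_mid.n_markers < 0.02
        assert post.h2 < 0.15

    def test_large_qtl_recovered_in_top_decile(self, geno_mid):
        """5 large QTL: at least 4 carry top-decile PIP."""
        rng = np.random.default_rng(61)
        X = gm.design_matrix(geno_mid, "standardized")
        causal = np.array([50, 210, 400, 570, 730])
        beta = np.zeros(geno_mid.n_markers)
        beta[causal] = rng.choice([-1, 1], 5) * 1.0
        g = X @ beta
        y = g + rng.normal(0, g.std() * 0.8, geno_mid.n_samples)
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=3, **CFG))
        thresh = np.quantile(post.pip, 0.9)
        assert np.sum(post.pip[causal] >= thresh) >= 4

    def test_single_group_rrc_matches_bayesr_predictions(self, geno_mid,
                                                         qtl_sim):
        y, _, _ = qtl_sim
        anno = AnnotationMap(
            "one", geno_mid.marker_ids.copy(),
            np.zeros(geno_mid.n_markers, dtype=np.int64), ["all"])
        a = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=5, **CFG))
        b = samplers.run_bayes_rr_rc(y, geno_mid, anno,
                                     cfg=McmcConfig(seed=6, **CFG))
        pa = samplers.predict_from_posterior(a, geno_mid)
        pb = samplers.predict_from_posterior(b, geno_mid)
        assert np.corrcoef(pa, pb)[0, 1] > 0.99

    def test_empty_group_dropped_with_warning(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        groups = np.zeros(geno_mid.n_markers, dtype=np.int64)
        anno = AnnotationMap("two", geno_mid.marker_ids.copy(), groups,
                             ["all", "empty"])
        with pytest.warns(UserWarning, match="empty annotation groups"):
            post = samplers.run_bayes_rr_rc(y, geno_mid, anno,
                                            cfg=McmcConfig(seed=1, **CFG))
        assert post.group_labels == ["all"]

    def test_zero_phenotype_degenerates(self, geno_mid):
        y = np.zeros(geno_mid.n_samples)
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=1, **CFG))
        pred = samplers.predict_from_posterior(post, geno_mid)
        assert float(np.max(np.abs(pred))) < 1e-3
        assert post.sigma2_groups[0] < 1e-6


class TestBslmm:
    def test_polygenic_architecture(self, geno_mid):
        """Pure polygenic signal: few additional effects, h2 recovered."""
        rng = np.random.default_rng(70)
        X = gm.design_matrix(geno_mid, "standardized")
        beta = rng.normal(0, 1, geno_mid.n_markers)
        g = X @ beta
        g = g / g.std() * np.sqrt(0.5 / 0.5)
        y = g + rng.normal(0, 1, geno_mid.n_samples)
        h2_true = np.var(g) / np.var(y)
        grm = gm.compute_grm(geno_mid, "centered")
        post = samplers.run_bslmm(y, geno_mid, grm,
                                  McmcConfig(seed=8, n_iter=800, burn_in=300))
        assert post.h2 == pytest.approx(h2_true, abs=0.1)
        mean_count = post.traces["n_additional"][300:].mean()
        assert mean_count < 0.1 * geno_mid.n_markers

    def test_sparse_off_matches_gblup(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        n = geno_mid.n_samples
        ref = np.arange(300)
        tgt = np.arange(300, n)
        ref_geno = geno_mid.subset_samples(
            [geno_mid.sample_ids[i] for i in ref])
        tgt_geno = geno_mid.subset_samples(
            [geno_mid.sample_ids[i] for i in tgt])
        grm_ref = gm.compute_grm(ref_geno, "centered")
        post = samplers.run_bslmm(y[ref], ref_geno, grm_ref,
                                  McmcConfig(seed=9, n_iter=800, burn_in=300),
                                  sparse=False)
        p_bslmm = samplers.predict_from_posterior(post, tgt_geno)
        grm_full = gm.compute_grm(geno_mid, "centered")
        vc = lmm.reml_fit(y[ref], [grm_full.values[np.ix_(ref, ref)]])
        p_blup = lmm.blup_predict(y[ref], grm_full, vc, ref, tgt)
        assert np.corrcoef(p_bslmm, p_blup)[0, 1] > 0.99
        assert np.all(post.beta_mean == 0)


class TestPrediction:
    def test_zero_effects_zero_predictions(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=1, **CFG))
        post.beta_mean = np.zeros_like(post.beta_mean)
        np.testing.assert_allclose(
            samplers.predict_from_posterior(post, geno_mid), 0.0)

    def test_matches_direct_multiplication(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=1, **CFG))
        sub = geno_mid.subset_samples(geno_mid.sample_ids[:10])
        pred = samplers.predict_from_posterior(post, sub)
        f = post.allele_freq
        X = (sub.imputed() - 2 * f) / np.sqrt(2 * f * (1 - f))
        np.testing.assert_allclose(pred, X @ post.beta_mean, atol=1e-10)

    def test_in_sample_correlates_with_signal(self, geno_mid, qtl_sim):
        y, _, g = qtl_sim
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=1, **CFG))
        pred = samplers.predict_from_posterior(post, geno_mid)
        assert np.corrcoef(pred, g)[0, 1] > 0.8

    def test_marker_mismatch_rejected(self, geno_mid, qtl_sim):
        y, _, _ = qtl_sim
        post = samplers.run_bayes_r(y, geno_mid, McmcConfig(seed=1, **CFG))
        with pytest.raises(ValueError, match="do not match"):
            samplers.predict_from_posterior(
                post, geno_mid.subset_markers(np.arange(10)))
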