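"""BayesR/BayesRC Gibbs samplers, GBLUP, and GBV prediction."""

import numpy as np
import pandas as pd
import pytest

from heatgp.errors import ConfigError, DataError
from heatgp.kinship import build_grm
from heatgp.predict import (
    McmcConfig,
    MixtureSpec,
    bull_weight,
    fit_bayesr,
    fit_bayesrc,
    fit_gblup,
    predict_gbv,
)
from tests.conftest import make_genotypes


class TestBullWeight:
    def test_matches_direct_evaluation(self):
        assert bull_weight(0.25, 0.2, 100) == pytest.approx(0.75 / (0.05 + 0.0375))
        assert bull_weight(0.25, 0.2, 1) == pytest.approx(0.75 / (0.05 + 3.75))

    def test_large_daughter_count_limit(self):
        assert bull_weight(0.25, 0.2, 10**9) == pytest.approx(15.0, rel=1e-6)

    def test_increases_with_daughter_count(self):
        ws = [bull_weight(0.3, 0.2, p) for p in (1, 5, 20, 100, 1000)]
        assert ws == sorted(ws)

    @pytest.mark.parametrize("h2", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_heritability_rejected(self, h2):
        with pytest.raises(ConfigError):
            bull_weight(h2)


class TestMcmcConfig:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ConfigError):
            McmcConfig(n_iter=100, burn_in=100)

    def test_paper_scale_defaults(self):
        cfg = McmcConfig()
        assert (cfg.n_chains, cfg.n_iter, cfg.burn_in) == (5, 40_000, 20_000)


def _ridge_posterior_mean(y, Wc, wts, prior_var, se2):
    """Closed-form weighted ridge with a flat-prior intercept."""
    n, m = Wc.shape
    X = np.ones((n, 1))
    D = np.diag(wts)
    A = np.block([[X.T @ D @ X, X.T @ D @ Wc],
                  [Wc.T @ D @ X, Wc.T @ D @ Wc + np.eye(m) * se2 / prior_var]])
    b = np.concatenate([X.T @ D @ y, Wc.T @ D @ y])
    return np.linalg.solve(A, b)[1:]


class TestBayesR:
    def test_forced_class_matches_conjugate_ridge_posterior(self):
        rng = np.random.default_rng(1)
        n, m = 60, 4
        W = rng.binomial(2, 0.5, (n, m)).astype(float)
        Wc = W - W.mean(0)
        wts = rng.uniform(0.5, 2.0, n)
        se2, sv2 = 1.0, 10.0
        y = Wc @ np.array([0.5, -0.3, 0.2, 0.0]) + rng.normal(0, np.sqrt(se2 / wts))
        post = fit_bayesr(
            y, W, weights=wts,
            mcmc=McmcConfig(n_chains=1, n_iter=40_000, burn_in=4_000, seed=0),
            forced_class=np.full(m, 3, dtype=np.int64),
            initial={"sigma_v2": sv2, "sigma_e2": se2},
            update_sigma_v2=False, update_sigma_e2=False, update_proportions=False)
        expect = _ridge_posterior_mean(y, Wc, wts, 0.01 * sv2, se2)
        assert np.allclose(post.snp_effect_mean, expect, rtol=0.02, atol=5e-4)

    def test_null_phenotype_implies_negligible_genetic_signal(self):
        """Under a pure-noise phenotype the zero class dominates and the
        posterior-mean effects explain almost none of the variance.  (The
        small-effect classes are likelihood-equivalent to the zero class
        at this scale, so their proportions stay prior-diffuse rather
        than vanishing; the implied variance is the identifiable check.)"""
        rng = np.random.default_rng(2)
        g = make_genotypes(400, 1000, seed=3)
        y = rng.standard_normal(400)
        post = fit_bayesr(y, g, mcmc=McmcConfig(n_chains=1, n_iter=2000,
                                                burn_in=1000, seed=1))
        assert post.mixture_proportions_mean[0, 0] == post.mixture_proportions_mean[0].max()
        implied = g.centered() @ post.snp_effect_mean
        assert implied.var() / y.var() < 0.05

    def test_equal_weights_match_rescaled_unweighted_run(self):
        rng = np.random.default_rng(4)
        n, m = 50, 30
        g = make_genotypes(n, m, seed=5)
        y = rng.standard_normal(n)
        mcmc = McmcConfig(n_chains=1, n_iter=500, burn_in=200, seed=7)
        a = fit_bayesr(y, g, weights=np.full(n, 2.0), mcmc=mcmc,
                       initial={"sigma_e2": 1.0})
        b = fit_bayesr(y, g, weights=None, mcmc=mcmc,
                       initial={"sigma_e2": 0.5})
        assert np.array_equal(a.snp_effect_mean, b.snp_effect_mean)
        assert a.sigma_e2_mean == pytest.approx(2 * b.sigma_e2_mean, rel=1e-12)

    def test_same_seed_bit_reproducible(self):
        rng = np.random.default_rng(6)
        g = make_genotypes(80, 50, seed=8)
        y = rng.standard_normal(80)
        mcmc = McmcConfig(n_chains=2, n_iter=400, burn_in=200, seed=3)
        a = fit_bayesr(y, g, mcmc=mcmc)
        b = fit_bayesr(y, g, mcmc=mcmc)
        assert np.array_equal(a.snp_effect_mean, b.snp_effect_mean)
        assert np.array_equal(a.class_prob, b.class_prob)

    def test_posterior_invariants(self):
        rng = np.random.default_rng(7)
        g = make_genotypes(100, 60, seed=9)
        eff = np.zeros(60)
        eff[:5] = 1.0
        y = g.centered() @ eff + rng.standard_normal(100)
        post = fit_bayesr(y, g, mcmc=McmcConfig(n_chains=2, n_iter=600,
                                                burn_in=300, seed=11))
        assert np.allclose(post.class_prob.sum(axis=1), 1.0)
        for tr in post.traces["sigma_v2"]:
            assert (tr > 0).all()
        for tr in post.traces["sigma_e2"]:
            assert (tr > 0).all()
        for tr in post.traces["proportions"]:
            assert np.allclose(tr.sum(axis=-1), 1.0)

    def test_nonpositive_weights_rejected(self):
        g = make_genotypes(20, 10, seed=10)
        with pytest.raises(DataError):
            fit_bayesr(np.ones(20), g, weights=np.zeros(20),
                       mcmc=McmcConfig(n_chains=1, n_iter=10, burn_in=5))

    def test_gibbs_class_frequencies_match_enumeration(self):
        """On a 3-SNP instance with fixed hyperparameters, the sampler's
        class-membership frequencies agree with direct enumeration of the
        4^3 discretised posterior."""
        rng = np.random.default_rng(12)
        n, m = 25, 3
        W = rng.binomial(2, [0.5, 0.3, 0.6], (n, m)).astype(float)
        Wc = W - W.mean(0)
        sv2, se2 = 5.0, 1.0
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        scalars = np.array(MixtureSpec().class_scalars)
        y = Wc @ np.array([0.6, 0.0, -0.4]) + rng.normal(0, 1, n)

        post = fit_bayesr(
            y, W, mcmc=McmcConfig(n_chains=1, n_iter=120_000, burn_in=5_000, seed=5),
            initial={"sigma_v2": sv2, "sigma_e2": se2, "pi": pi.reshape(1, 4)},
            update_sigma_v2=False, update_sigma_e2=False, update_proportions=False)

        # enumeration oracle: marginal likelihood of every class config,
        # intercept integrated with a flat prior
        X = np.ones((n, 1))
        logpost = np.full((4, 4, 4), -np.inf)
        for idx in np.ndindex(4, 4, 4):
            S = np.diag(scalars[list(idx)] * sv2)
            Sigma = Wc @ S @ Wc.T + se2 * np.eye(n)
            Si = np.linalg.inv(Sigma)
            B = X.T @ Si @ X
            Q = Si - Si @ X @ np.linalg.inv(B) @ X.T @ Si
            _, ld = np.linalg.slogdet(Sigma)
            _, ldB = np.linalg.slogdet(B)
            logpost[idx] = (np.sum(np.log(pi[list(idx)]))
                            - 0.5 * (ld + ldB + y @ Q @ y))
        p = np.exp(logpost - logpost.max())
        p /= p.sum()
        marg = [p.sum(axis=tuple(a for a in range(3) if a != j)) for j in range(3)]
        for j in range(3):
            assert np.allclose(post.class_prob[j], marg[j], atol=0.025)


class TestBayesRC:
    def test_single_class_reduces_to_bayesr(self):
        rng = np.random.default_rng(13)
        g = make_genotypes(60, 40, seed=14)
        y = rng.standard_normal(60)
        mcmc = McmcConfig(n_chains=1, n_iter=400, burn_in=200, seed=9)
        a = fit_bayesr(y, g, mcmc=mcmc)
        b = fit_bayesrc(y, g, classes=np.zeros(40, dtype=int), mcmc=mcmc)
        assert np.array_equal(a.snp_effect_mean, b.snp_effect_mean)

    def test_null_class_concentrates_on_zero_component(self):
        rng = np.random.default_rng(15)
        g = make_genotypes(300, 400, seed=16)
        eff = np.zeros(400)
        qtl = np.arange(0, 40)           # class I carries all the signal
        eff[qtl] = rng.normal(0, 0.3, 40)
        y = g.centered() @ eff + rng.standard_normal(300)
        annot = np.zeros(400, dtype=int)
        annot[350:] = 1                  # class II: pure null SNPs
        post = fit_bayesrc(y, g, classes=annot,
                           mcmc=McmcConfig(n_chains=1, n_iter=1500,
                                           burn_in=700, seed=10))
        # the null class contributes essentially no genetic variance and
        # its zero component carries the most mass
        pi2 = post.mixture_proportions_mean[1]
        assert pi2[0] == pi2.max()
        Z = g.centered()
        var_null = (Z[:, annot == 1] @ post.snp_effect_mean[annot == 1]).var()
        var_sig = (Z[:, annot == 0] @ post.snp_effect_mean[annot == 0]).var()
        assert var_null < 0.1 * var_sig

    def test_empty_class_ignored_with_warning(self, caplog):
        rng = np.random.default_rng(17)
        g = make_genotypes(40, 20, seed=18)
        annot = np.zeros(20, dtype=int)
        annot[:5] = 2                    # class 1 empty
        post = fit_bayesrc(rng.standard_normal(40), g, classes=annot,
                           mcmc=McmcConfig(n_chains=1, n_iter=100, burn_in=50))
        assert post.mixture_proportions_mean.shape[0] == 2


class TestPredictGbv:
    def test_zero_effects_give_zero_gbv(self):
        g = make_genotypes(30, 20, seed=19)
        post = fit_bayesr(np.zeros(30) + 1e-9 * np.arange(30), g,
                          mcmc=McmcConfig(n_chains=1, n_iter=50, burn_in=20))
        post.snp_effect_mean[:] = 0.0
        gbv = predict_gbv(post, g)
        assert np.allclose(gbv, 0.0)

    def test_single_snp_arithmetic(self):
        g_ref = make_genotypes(40, 1, seed=20, freq_range=(0.5, 0.5))
        post = fit_bayesr(np.random.default_rng(0).standard_normal(40), g_ref,
                          mcmc=McmcConfig(n_chains=1, n_iter=50, burn_in=20))
        post.snp_effect_mean[:] = 1.0
        post.ref_freq[:] = 0.5           # reference mean dosage 1.0
        val = make_genotypes(3, 1, seed=21)
        val.dosages[:, 0] = [0, 1, 2]
        gbv = predict_gbv(post, val)
        assert np.allclose(gbv.to_numpy(), [-1.0, 0.0, 1.0])

    def test_duplicate_individuals_identical_gbv(self):
        g = make_genotypes(50, 30, seed=22)
        post = fit_bayesr(np.random.default_rng(1).standard_normal(50), g,
                          mcmc=McmcConfig(n_chains=1, n_iter=200, burn_in=100))
        val = make_genotypes(4, 30, seed=23)
        val.dosages[1] = val.dosages[0]
        gbv = predict_gbv(post, val)
        assert gbv.iloc[0] == gbv.iloc[1]

    def test_snp_mismatch_rejected(self):
        g = make_genotypes(30, 10, seed=24)
        post = fit_bayesr(np.random.default_rng(2).standard_normal(30), g,
                          mcmc=McmcConfig(n_chains=1, n_iter=50, burn_in=20))
        other = make_genotypes(5, 9, seed=25)
        with pytest.raises(DataError):
            predict_gbv(post, other)


def _gblup_data(seed, n_ref=150, n_val=60, m=300, h2=0.5):
    g = make_genotypes(n_ref + n_val, m, seed=seed)
    rng = np.random.default_rng(seed + 1)
    eff = rng.normal(0, 1, m) * (rng.random(m) < 0.1)
    tbv = g.centered() @ eff
    tbv = tbv / tbv.std() * np.sqrt(h2)
    y_all = tbv + rng.normal(0, np.sqrt(1 - h2), n_ref + n_val)
    G = build_grm(g)
    ref = g.individual_ids[:n_ref]
    y = pd.Series(y_all[:n_ref], index=ref)
    return g, G, y, tbv


class TestGblup:
    def test_two_identical_kernels_sum_to_single_kernel_gbv(self):
        g, G, y, _ = _gblup_data(30)
        gbv1, _ = fit_gblup(y, grms=G)
        gbv2, comps = fit_gblup(y, grms=[G, G])
        assert np.allclose(gbv1.to_numpy(), gbv2.to_numpy(), atol=1e-5)

    def test_matches_snp_blup_ridge_equivalence(self):
        g, G, y, _ = _gblup_data(31)
        gbv, comps = fit_gblup(y, grms=G)
        sg, se = comps[0].sigma_g2, comps[0].sigma_e2
        p = g.allele_freq
        denom = 2 * float(np.sum(p * (1 - p)))
        Z = g.centered()
        n_ref = len(y)
        Zr = Z[:n_ref]
        V = sg * Zr @ Zr.T / denom + se * np.eye(n_ref)
        X = np.ones((n_ref, 1))
        Vinv = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y.to_numpy())
        v_hat = (sg / denom) * Zr.T @ Vinv @ (y.to_numpy() - X @ b)
        assert np.allclose(gbv.to_numpy(), Z @ v_hat, atol=1e-6)

    def test_pure_noise_gives_near_zero_gbv(self):
        g = make_genotypes(120, 200, seed=32)
        rng = np.random.default_rng(33)
        y = pd.Series(rng.standard_normal(120), index=g.individual_ids)
        gbv, comps = fit_gblup(y, grms=build_grm(g))
        assert np.std(gbv) < 0.2

    def test_kernel_dimension_mismatch_rejected(self):
        g, G, y, _ = _gblup_data(34)
        g2 = make_genotypes(50, 100, seed=35)
        with pytest.raises(DataError):
            fit_gblup(y, grms=[G, build_grm(g2)])

    def test_weighted_fit_runs_and_predicts(self):
        g, G, y, tbv = _gblup_data(36)
        rng = np.random.default_rng(37)
        w = rng.uniform(0.5, 4.0, len(y))
        gbv, comps = fit_gblup(y, weights=w, grms=G)
        r = np.corrcoef(gbv.to_numpy()[len(y):], tbv[len(y):])[0, 1]
        assert r > 0.3
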