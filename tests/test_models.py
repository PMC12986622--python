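"""Tests of the marker-effect models and PCA-feature regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ricegs import (GenotypeMatrix, McmcConfig, fit_bayes_lasso, fit_gblup,
                    fit_pc_regressor, pc_features, predict_gebv)
from ricegs.models import register_backend
from .test_genio import make_matrix


def random_panel(n, m, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    return make_matrix(rng.binomial(2, p, size=(n, m)).astype(float))


def polygenic_y(G, h2, n_qtl, seed):
    rng = np.random.default_rng(seed)
    qtl = rng.choice(G.n_variants, n_qtl, replace=False)
    u = (G.dosages[:, qtl] - G.dosages[:, qtl].mean(0)) @ rng.normal(size=n_qtl)
    e = rng.normal(size=G.n_samples)
    e *= np.sqrt(np.var(u) * (1 - h2) / h2 / np.var(e))
    return u + e


class TestMcmcConfig:
    @given(st.integers(2, 5000), st.integers(1, 4999), st.integers(1, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_retention_arithmetic(self, n_iter, burn_in, thin):
        if burn_in >= n_iter:
            burn_in = n_iter - 1
        cfg = McmcConfig(n_iter=n_iter, burn_in=burn_in, thin=thin)
        assert cfg.n_retained == (n_iter - burn_in) // thin

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(thin=0)


class TestGblup:
    def test_constant_phenotype_gives_zero_effects(self):
        G = random_panel(20, 30, seed=0)
        fit = fit_gblup(G, np.full(20, 3.7))
        assert fit.mu == pytest.approx(3.7, abs=1e-12)
        np.testing.assert_allclose(fit.marker_effects, 0.0, atol=1e-8)
        pred = predict_gebv(fit, G)
        np.testing.assert_allclose(pred.gebv, 3.7, atol=1e-10)

    def test_marker_space_equals_kinship_space_blup(self):
        """Ridge on centered markers must reproduce GRM-space BLUP."""
        G_all = random_panel(70, 200, seed=1)
        y_all = polygenic_y(G_all, 0.6, 40, seed=2)
        train, test = np.arange(50), np.arange(50, 70)
        G_train = G_all.take_samples(train)
        y = y_all[train]
        fit = fit_gblup(G_train, y)
        marker_pred = predict_gebv(fit, G_all.take_samples(test)).gebv

        # independent kinship-space oracle with matched shrinkage
        Xc_train = G_train.dosages - G_train.dosages.mean(0)
        Xc_test = G_all.take_samples(test).dosages - G_train.dosages.mean(0)
        p = G_train.dosages.mean(0) / 2
        c = 2 * np.sum(p * (1 - p))
        K_tr = Xc_train @ Xc_train.T / c
        K_te = Xc_test @ Xc_train.T / c
        vc = fit.variance_components
        lam = vc.sigma_e2 / vc.sigma_g2
        u = K_te @ np.linalg.solve(K_tr + lam * np.eye(50), y - y.mean())
        np.testing.assert_allclose(marker_pred, y.mean() + u, atol=1e-6)

    def test_duplicated_training_samples_get_identical_fits(self):
        G = random_panel(30, 50, seed=3)
        dosages = G.dosages.copy()
        dosages[29] = dosages[0]
        G = make_matrix(dosages)
        y = polygenic_y(G, 0.7, 20, seed=4)
        y[29] = y[0]
        fit = fit_gblup(G, y)
        pred = predict_gebv(fit, G)
        assert pred.gebv[0] == pytest.approx(pred.gebv[29], abs=1e-8)

    def test_mcmc_mode_deterministic_and_close_to_reml(self):
        G = random_panel(60, 40, seed=5)
        y = polygenic_y(G, 0.7, 20, seed=6)
        cfg = McmcConfig(n_iter=2000, burn_in=500, thin=5, seed=11)
        fit1 = fit_gblup(G, y, mode="mcmc", mcmc=cfg)
        fit2 = fit_gblup(G, y, mode="mcmc", mcmc=cfg)
        np.testing.assert_array_equal(fit1.marker_effects,
                                      fit2.marker_effects)
        reml = fit_gblup(G, y)
        r = np.corrcoef(predict_gebv(fit1, G).gebv,
                        predict_gebv(reml, G).gebv)[0, 1]
        assert r > 0.98

    def test_too_few_samples_rejected(self):
        G = random_panel(5, 10, seed=0)
        with pytest.raises(ValueError):
            fit_gblup(G, np.arange(5.0))


class TestBayesLasso:
    def test_default_schedule_retains_2000(self):
        assert McmcConfig().n_retained == 2000

    def test_deterministic_given_seed(self):
        G = random_panel(30, 20, seed=7)
        y = polygenic_y(G, 0.6, 10, seed=8)
        cfg = McmcConfig(n_iter=400, burn_in=100, thin=2, seed=3)
        f1 = fit_bayes_lasso(G, y, cfg)
        f2 = fit_bayes_lasso(G, y, cfg)
        np.testing.assert_array_equal(f1.marker_effects, f2.marker_effects)
        assert f1.posterior["n_retained"] == 150

    def test_huge_fixed_lambda2_shrinks_toward_zero(self):
        G = random_panel(50, 10, seed=9)
        y = polygenic_y(G, 0.8, 5, seed=10)
        cfg = McmcConfig(n_iter=2000, burn_in=500, thin=1, seed=1)
        shrunk = fit_bayes_lasso(G, y, cfg, lambda2_fixed=1e12)
        Xc = G.dosages - G.dosages.mean(0)
        ols, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(50), Xc]), y, rcond=None)
        assert np.all(np.abs(shrunk.marker_effects)
                      < 1e-3 * np.maximum(np.abs(ols[1:]), 1e-6))

    def test_shrinkage_nonincreasing_in_lambda2(self):
        G = random_panel(40, 15, seed=11)
        y = polygenic_y(G, 0.7, 8, seed=12)
        grids = []
        for lam2 in (1.0, 1e3, 1e6):
            vals = []
            for seed in range(5):
                cfg = McmcConfig(n_iter=800, burn_in=300, thin=1, seed=seed)
                f = fit_bayes_lasso(G, y, cfg, lambda2_fixed=lam2)
                vals.append(np.abs(f.marker_effects).mean())
            grids.append(np.mean(vals))
        assert grids[0] >= grids[1] >= grids[2]

    def test_two_chains_agree_within_monte_carlo_error(self):
        G = random_panel(40, 8, seed=13)
        y = polygenic_y(G, 0.8, 4, seed=14)
        fits = []
        for seed in (101, 202):
            cfg = McmcConfig(n_iter=50000, burn_in=10000, thin=10, seed=seed)
            fits.append(fit_bayes_lasso(G, y, cfg))
        k = fits[0].posterior["n_retained"]
        for j in range(8):
            # generous ESS discount for autocorrelation in the thinned chain
            mcse = np.hypot(fits[0].posterior["effect_sd"][j],
                            fits[1].posterior["effect_sd"][j]) / np.sqrt(k / 10)
            diff = abs(fits[0].marker_effects[j] - fits[1].marker_effects[j])
            assert diff < 3 * mcse + 1e-8


class TestPcFeatures:
    def test_full_variance_target_recovers_rank(self):
        rng = np.random.default_rng(15)
        # rank-4 dosage structure: 4 distinct accession profiles repeated
        profiles = rng.integers(0, 3, size=(4, 40)).astype(float)
        dosages = profiles[rng.integers(0, 4, size=30)]
        feats, proj = pc_features(make_matrix(dosages), variance_target=1.0)
        assert proj.k <= 4  # centered rank at most n_profiles
        np.testing.assert_allclose(np.var(feats, axis=0, ddof=1), 1.0,
                                   atol=1e-8)

    def test_projection_round_trip(self, panel):
        feats, proj = pc_features(panel, variance_target=0.9)
        again = proj.transform(panel.dosages)
        np.testing.assert_allclose(feats, again, atol=1e-8)

    def test_planted_rank_detected_at_95(self):
        # 10 distinct accession profiles repeated: centered rank <= 10, so
        # 95% of the variance needs at most 10 (+1 slack) components
        rng = np.random.default_rng(16)
        profiles = rng.integers(0, 3, size=(10, 200)).astype(float)
        dosages = profiles[rng.integers(0, 10, size=120)]
        feats, proj = pc_features(make_matrix(dosages), variance_target=0.95)
        assert proj.k <= 11

    def test_invalid_target_rejected(self, panel):
        with pytest.raises(ValueError):
            pc_features(panel, variance_target=0.0)
        with pytest.raises(ValueError):
            pc_features(panel, variance_target=1.5)


class TestPcRegressor:
    def test_ols_backend_matches_direct_least_squares(self):
        G = random_panel(60, 30, seed=17)
        y = polygenic_y(G, 0.8, 10, seed=18)
        feats, proj = pc_features(G, 0.95)
        fit = fit_pc_regressor(feats, y, backend="ols", projection=proj,
                               snp_keys=G.variant_keys())
        pred = predict_gebv(fit, G).gebv
        A = np.column_stack([np.ones(len(y)), feats])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(pred, A @ beta, atol=1e-8)

    def test_mean_backend_predicts_grand_mean(self):
        G = random_panel(30, 20, seed=19)
        y = polygenic_y(G, 0.5, 5, seed=20)
        feats, proj = pc_features(G, 0.9)
        fit = fit_pc_regressor(feats, y, backend="mean", projection=proj,
                               snp_keys=G.variant_keys())
        np.testing.assert_allclose(predict_gebv(fit, G).gebv, y.mean())

    def test_backend_swap_keeps_projection(self):
        G = random_panel(30, 20, seed=21)
        y = polygenic_y(G, 0.5, 5, seed=22)
        feats, proj = pc_features(G, 0.9)
        f1 = fit_pc_regressor(feats, y, "ols", projection=proj)
        f2 = fit_pc_regressor(feats, y, "mean", projection=proj)
        assert f1.projection is proj and f2.projection is proj

    def test_unregistered_backend_rejected(self):
        with pytest.raises(KeyError, match="unregistered"):
            fit_pc_regressor(np.zeros((10, 2)), np.zeros(10),
                             backend="no_such_backend")

    def test_custom_backend_registration(self):
        class Doubler:
            def fit(self, F, y):
                return self

            def predict(self, F):
                return np.full(len(F), 2.0)

        register_backend("doubler", lambda **kw: Doubler())
        G = random_panel(15, 10, seed=23)
        feats, proj = pc_features(G, 0.9)
        fit = fit_pc_regressor(feats, np.arange(15.0), "doubler",
                               projection=proj)
        np.testing.assert_allclose(predict_gebv(fit, G).gebv, 2.0)


class TestPredictGebv:
    def test_centered_zero_genotype_predicts_mu(self):
        # panel whose columns all average to dosage 1: a new all-het sample
        # sits exactly at the training means, so its centered genotype is 0
        rng = np.random.default_rng(24)
        col = np.repeat([0.0, 2.0], 10)
        G = make_matrix(np.column_stack(
            [rng.permutation(col) for _ in range(10)]))
        y = polygenic_y(G, 0.6, 5, seed=25)
        fit = fit_gblup(G, y)
        new = GenotypeMatrix(["new"], G.variants, np.ones((1, 10)))
        assert predict_gebv(fit, new).gebv[0] == pytest.approx(fit.mu)

    def test_all_zero_effects_predict_mu(self):
        G = random_panel(15, 10, seed=26)
        fit = fit_gblup(G, np.full(15, 1.25))
        np.testing.assert_allclose(predict_gebv(fit, G).gebv, 1.25)

    def test_missing_variant_keys_listed(self):
        G = random_panel(20, 10, seed=27)
        y = polygenic_y(G, 0.6, 5, seed=28)
        fit = fit_gblup(G, y)
        with pytest.raises(KeyError, match="absent"):
            predict_gebv(fit, G.take_variants(range(5)))

    def test_in_sample_fit_beats_out_of_sample(self):
        G = random_panel(120, 150, seed=29)
        y = polygenic_y(G, 0.5, 40, seed=30)
        train, test = np.arange(90), np.arange(90, 120)
        fit = fit_gblup(G.take_samples(train), y[train])
        r_in = np.corrcoef(predict_gebv(fit, G.take_samples(train)).gebv,
                           y[train])[0, 1]
        r_out = np.corrcoef(predict_gebv(fit, G.take_samples(test)).gebv,
                            y[test])[0, 1]
        assert r_in >= r_out
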