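import numpy as np
import pytest

from healthdea.sdm import (
    SpatialDurbinFE, SpatialErrorFE, _within_twoway, effects_decomposition,
    hausman_test, lm_tests, lr_wald_tests, panel_hausman,
)
from healthdea.synthetic import SyntheticSDMConfig, generate_sdm_panel


def simulate(W, **kw):
    cfg = SyntheticSDMConfig(**kw)
    Xpos, y, truth = generate_sdm_panel(cfg, W)
    return np.log(Xpos), y, truth


class TestWithinTransform:
    def test_idempotent(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((6, 9))
        once = _within_twoway(a)
        assert np.allclose(_within_twoway(once), once)

    def test_absorbs_additive_effects(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((6, 9))
        mu = rng.standard_normal(9)
        v = rng.standard_normal(6)
        assert np.allclose(_within_twoway(a + mu[None, :] + v[:, None]),
                           _within_twoway(a))


class TestSpatialDurbinFit:
    def test_collapses_to_within_ols_when_no_spatial_terms(self, grid7):
        X, y, truth = simulate(grid7, rho=0.0, eta=(0.0, 0.0), seed=5)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        # within OLS on demeaned data, same regressor set
        from healthdea.sdm import _spatial_lag
        Xf = np.concatenate([X, _spatial_lag(X, grid7.matrix)], axis=2)
        Xt = _within_twoway(Xf).reshape(-1, 4)
        yt = _within_twoway(y).ravel()
        wyt = _within_twoway(_spatial_lag(y, grid7.matrix)).ravel()
        b_ols = np.linalg.lstsq(Xt, yt - fit.rho_ * wyt, rcond=None)[0]
        assert np.allclose(fit.coef_, b_ols, atol=1e-6)
        se = fit.bse_[1:3]
        assert np.all(np.abs(fit.beta_ - truth["beta"]) < 3 * se)

    def test_noiseless_limit_recovers_beta_exactly(self, grid7):
        X, y, _ = simulate(grid7, rho=0.0, eta=(0.0, 0.0), sigma=0.0,
                           unit_effect_sd=0.0, time_effect_sd=0.0, seed=2)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        # rho is not identified here: W y lies in the span of the Durbin
        # regressors when y = X beta exactly, so only beta is pinned down
        assert np.allclose(fit.beta_, [-0.6, 0.3], atol=1e-8)

    def test_optimum_beats_rho_zero(self, grid7):
        X, y, _ = simulate(grid7, rho=0.4, seed=3)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        pinned = SpatialDurbinFE(grid7, rho_interval=(-1e-9, 1e-9)).fit(X, y)
        assert fit.loglik_ >= pinned.loglik_

    def test_parameter_recovery_across_replicates(self, grid7):
        rhos = []
        for rep in range(25):
            X, y, _ = simulate(grid7, seed=500 + rep)
            rhos.append(SpatialDurbinFE(grid7).fit(X, y).rho_)
        assert 0.35 <= np.mean(rhos) <= 0.45

    def test_sign_recovery_at_study_scale(self, china_weights):
        # 31-unit contiguity, T=12, coefficient magnitudes typical of a
        # provincial efficiency regression on five logged covariates
        beta = (-0.66, -0.30, -0.18, -0.04, 0.26)
        eta = (1.20, -0.53, -0.31, -0.11, 0.37)
        hits = np.zeros(6)
        n_rep = 40
        for rep in range(n_rep):
            X, y, _ = simulate(china_weights, rho=0.3, beta=beta, eta=eta,
                               n_units=31, seed=900 + rep)
            fit = SpatialDurbinFE(china_weights).fit(X, y)
            signs = np.sign(np.concatenate([fit.beta_[[0, 1, 4]],
                                            fit.eta_[[0, 1, 4]]]))
            want = np.sign(np.array([beta[0], beta[1], beta[4],
                                     eta[0], eta[1], eta[4]]))
            hits += signs == want
        assert np.all(hits / n_rep >= 0.9)


class TestEffects:
    def test_rho_zero_closed_form(self, grid7):
        X, y, _ = simulate(grid7, rho=0.0, seed=4)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        fit.rho_ = 0.0   # evaluate the closed form at exactly rho = 0
        eff = effects_decomposition(fit, n_draws=10, seed=0)
        assert np.allclose(eff["direct"], fit.beta_, atol=1e-12)
        assert np.allclose(eff["indirect"], fit.eta_, atol=1e-12)

    def test_additivity_exact(self, grid7):
        X, y, _ = simulate(grid7, seed=6)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        eff = effects_decomposition(fit, n_draws=50, seed=1)
        dev = (eff["direct"] + eff["indirect"] - eff["total"]).abs().max()
        assert dev < 1e-14

    def test_seeded_draws_reproducible(self, grid7):
        X, y, _ = simulate(grid7, seed=7)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        e1 = effects_decomposition(fit, n_draws=50, seed=3)
        e2 = effects_decomposition(fit, n_draws=50, seed=3)
        assert np.array_equal(e1["direct_se"], e2["direct_se"])


class TestLMBattery:
    def test_statistics_nonnegative(self, grid7):
        X, y, _ = simulate(grid7, seed=8)
        for stat, p in lm_tests(X, y, grid7).values():
            assert stat >= 0
            assert 0 <= p <= 1

    def test_lag_dgp_favors_lag_statistic(self, grid7):
        wins = 0
        for rep in range(50):
            X, y, _ = simulate(grid7, rho=0.6, eta=(0.0, 0.0), seed=700 + rep)
            t = lm_tests(X, y, grid7)
            wins += t["lm_lag"][0] > t["lm_error"][0]
        assert wins / 50 >= 0.8


class TestLRWald:
    def test_df_equals_covariate_count(self, grid7):
        X, y, _ = simulate(grid7, seed=9)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        out = lr_wald_tests(fit, X, y)
        assert out["df"] == 2

    def test_lr_nonnegative_under_nesting(self, grid7):
        X, y, _ = simulate(grid7, seed=10)
        fit = SpatialDurbinFE(grid7).fit(X, y)
        out = lr_wald_tests(fit, X, y)
        assert out["lr_lag"][0] >= 0
        assert out["lr_error"][0] >= 0
        assert "lr_lag_nonconvergence" not in out

    def test_sem_fit_converges(self, grid7):
        X, y, _ = simulate(grid7, seed=11)
        sem = SpatialErrorFE(grid7).fit(X, y)
        assert sem.converged_
        assert np.isfinite(sem.loglik_)


class TestHausman:
    def test_identical_estimates_give_zero(self):
        b = np.array([0.5, -0.2])
        V1 = np.diag([0.02, 0.03])
        V2 = np.diag([0.01, 0.01])
        stat, df, p, _ = hausman_test(b, V1, b, V2)
        assert stat == 0.0
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hausman_test([1.0], np.eye(1), [1.0, 2.0], np.eye(2))

    def test_power_under_correlated_unit_effects(self):
        rng = np.random.default_rng(4)
        n, T = 49, 12
        rejections = 0
        for rep in range(100):
            u = rng.standard_normal(n)
            x1 = 0.7 * u[None, :] + np.sqrt(0.51) * rng.standard_normal((T, n))
            x2 = rng.standard_normal((T, n))
            X = np.stack([x1, x2], axis=2)
            y = (0.5 * x1 - 0.3 * x2 + u[None, :]
                 + 0.5 * rng.standard_normal((T, n)))
            rejections += panel_hausman(X, y, n)["p_value"] <= 0.05
        assert rejections / 100 >= 0.8
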