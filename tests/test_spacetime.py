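"""Space-time ozone model: covariance, likelihood, MCMC and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from ozoneimpact import exposure, synthetic
from ozoneimpact.spacetime import (GPPriors, LinkedPanel, STCovarianceParams,
                                   _reflect, effective_range, fit_mcmc,
                                   log_likelihood, predict,
                                   residual_correlation, validate_holdout)

PAPER_PARAMS = STCovarianceParams(sigma2=110.25, rho_s=179.0, rho_t=1.83)


def make_panel(n_s, n_t, seed=0, sigma2=110.25, rho_s=179.0, rho_t=1.83,
               missing_frac=0.0):
    stations, _ = synthetic.generate_network(n_stations=n_s, n_communities=1,
                                             seed=seed)
    truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                    seed=seed, sigma2=sigma2, rho_s=rho_s,
                                    rho_t=rho_t)
    dates = exposure.summer_dates(2000)[:n_t]
    weather = synthetic.generate_weather(stations, dates, seed=seed)
    ozone = synthetic.generate_ozone(stations, weather, truth, seed=seed)
    panel = synthetic.assemble_panel(stations, weather, ozone)
    if missing_frac > 0:
        r = np.random.default_rng(seed + 1)
        mask = r.random(panel.Y.shape) < missing_frac
        mask[0, 0] = False  # keep at least one observation
        panel.Y[mask] = np.nan
    return panel, truth


class TestResidualCorrelation:
    def test_one_day_lag_at_reported_decay(self):
        # temporal decay scale 1.83 days -> 0.58 between consecutive days
        assert residual_correlation(PAPER_PARAMS, 0.0, 1.0) == pytest.approx(
            0.58, abs=0.005)

    def test_100km_at_reported_decay(self):
        # spatial decay scale 179 km -> 0.57 at 100 km separation
        assert residual_correlation(PAPER_PARAMS, 100.0, 0.0) == pytest.approx(
            0.57, abs=0.005)

    def test_zero_separation_is_one(self):
        assert residual_correlation(PAPER_PARAMS, 0.0, 0.0) == 1.0

    def test_monotone_and_separable(self):
        d = np.linspace(0, 500, 30)
        c_space = residual_correlation(PAPER_PARAMS, d, 0.0)
        assert np.all(np.diff(c_space) < 0)
        h = np.linspace(0, 10, 30)
        c_time = residual_correlation(PAPER_PARAMS, 0.0, h)
        assert np.all(np.diff(c_time) < 0)
        both = residual_correlation(PAPER_PARAMS, 123.0, 2.5)
        assert both == pytest.approx(
            residual_correlation(PAPER_PARAMS, 123.0, 0.0)
            * residual_correlation(PAPER_PARAMS, 0.0, 2.5))

    def test_negative_distance_errors(self):
        with pytest.raises(ValueError):
            residual_correlation(PAPER_PARAMS, -1.0, 0.0)


class TestEffectiveRange:
    def test_prior_bound_ranges(self):
        assert effective_range(350.0) == 1050.0
        assert effective_range(5.0) == 15.0
        assert effective_range(1.0) == 3.0

    def test_correlation_at_effective_range(self):
        p = STCovarianceParams(1.0, 179.0, 1.83)
        r = residual_correlation(p, effective_range(179.0), 0.0)
        assert r == pytest.approx(0.05, abs=0.002)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            effective_range(0.0)


class TestLogLikelihood:
    def test_single_observation_closed_form(self):
        panel = LinkedPanel(
            station_ids=np.array(["s1"]), coords=np.zeros((1, 2)),
            states=np.array(["A"]), dates=np.array(["2000-06-01"]),
            day_index=np.array([0]), Y=np.zeros((1, 1)),
            W=np.zeros((1, 1, 3)))
        beta = np.zeros(4)
        ll = log_likelihood(panel, beta, STCovarianceParams(1.0, 10.0, 1.0))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    @pytest.mark.parametrize("n_s,n_t", [(2, 3), (4, 5), (6, 8)])
    def test_kronecker_equals_dense_mvn(self, n_s, n_t):
        panel, truth = make_panel(n_s, n_t, seed=n_s * 10 + n_t)
        beta = truth.beta_flat(panel.state_levels)
        params = PAPER_PARAMS
        ll = log_likelihood(panel, beta, params)
        # oracle: dense multivariate normal over the vectorised panel
        Rs = np.exp(-panel.distance_matrix() / params.rho_s)
        Rt = np.exp(-panel.lag_matrix() / params.rho_t)
        cov = params.sigma2 * np.kron(Rs, Rt)
        resid = (panel.Y - panel.design_tensor() @ beta).ravel()
        want = multivariate_normal.logpdf(resid, mean=np.zeros(resid.size),
                                          cov=cov)
        assert ll == pytest.approx(want, abs=1e-8)

    def test_independence_limit(self):
        panel, truth = make_panel(3, 4, seed=5)
        beta = truth.beta_flat(panel.state_levels)
        params = STCovarianceParams(4.0, 1e-6, 1e-6)
        ll = log_likelihood(panel, beta, params)
        resid = (panel.Y - panel.design_tensor() @ beta).ravel()
        want = norm.logpdf(resid, scale=2.0).sum()
        assert ll == pytest.approx(want, rel=1e-9)

    def test_incomplete_panel_matches_observed_subset_oracle(self):
        panel, truth = make_panel(4, 5, seed=9, missing_frac=0.3)
        beta = truth.beta_flat(panel.state_levels)
        params = PAPER_PARAMS
        ll = log_likelihood(panel, beta, params)
        obs = np.isfinite(panel.Y)
        si, ti = np.where(obs)
        pts = panel.coords[si]
        t = panel.day_index[ti].astype(float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        h = np.abs(t[:, None] - t[None, :])
        cov = params.sigma2 * np.exp(-d / params.rho_s - h / params.rho_t)
        resid = (panel.Y - panel.design_tensor() @ beta)[si, ti]
        want = multivariate_normal.logpdf(resid, mean=np.zeros(resid.size),
                                          cov=cov)
        assert ll == pytest.approx(want, abs=1e-8)

    def test_nonfinite_beta_errors(self):
        panel, _ = make_panel(2, 3, seed=1)
        with pytest.raises(ValueError):
            log_likelihood(panel, np.full(8, np.nan), PAPER_PARAMS)


class TestReflection:
    @pytest.mark.parametrize("x", [-3.7, 0.0, 0.4, 1.0, 2.3, 11.9])
    def test_folds_into_interval(self, x):
        z = _reflect(x, 0.0, 1.0)
        assert 0.0 <= z <= 1.0

    def test_interior_unchanged(self):
        assert _reflect(0.3, 0.0, 1.0) == pytest.approx(0.3)
        assert _reflect(1.2, 0.0, 1.0) == pytest.approx(0.8)


class TestMCMC:
    def test_same_seed_identical_draws(self, gp_panel):
        a = fit_mcmc(gp_panel, n_iter=200, burn_in=50, seed=3)
        b = fit_mcmc(gp_panel, n_iter=200, burn_in=50, seed=3)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.rho_s, b.rho_s)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_acceptance_rate_in_window(self, gp_panel):
        post = fit_mcmc(gp_panel, n_iter=1500, burn_in=500, seed=5)
        assert 0.1 < post.accept_rate < 0.6

    def test_posterior_mean_matches_gls_in_iid_regime(self):
        # nearly independent residuals: posterior beta should agree with
        # the closed-form generalised least squares estimate
        panel, truth = make_panel(10, 30, seed=13, sigma2=9.0,
                                  rho_s=10.5, rho_t=0.01)
        post = fit_mcmc(panel, n_iter=1500, burn_in=500, seed=13)
        X = panel.design_tensor().reshape(-1, post.beta.shape[1])
        y = panel.Y.ravel()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        sd = post.beta.std(axis=0, ddof=1)
        assert np.all(np.abs(post.beta.mean(axis=0) - ols) < 4 * sd + 1e-3)

    def test_prior_only_run_reproduces_uniform_priors(self):
        panel, _ = make_panel(4, 6, seed=2)
        post = fit_mcmc(panel, n_iter=21000, burn_in=1000, seed=4,
                        sample_prior_only=True)
        pri = GPPriors()
        lo, hi = pri.rho_s_range
        assert post.rho_s.mean() == pytest.approx((lo + hi) / 2, abs=8.0)
        assert post.rho_s.std() == pytest.approx((hi - lo) / np.sqrt(12),
                                                 abs=8.0)
        lo_t, hi_t = pri.rho_t_range
        assert post.rho_t.mean() == pytest.approx((lo_t + hi_t) / 2, abs=0.15)

    def test_small_panel_errors(self):
        panel, _ = make_panel(3, 5, seed=1)
        single = panel.subset_stations(np.array([True, False, False]))
        with pytest.raises(ValueError):
            fit_mcmc(single, n_iter=100, burn_in=10, seed=0)

    def test_draw_table_layout(self, gp_panel):
        post = fit_mcmc(gp_panel, n_iter=120, burn_in=20, seed=8)
        frame = post.to_frame()
        assert set(frame.columns) == {"iter", "parameter", "value"}
        assert frame["iter"].max() == post.n_draws - 1
        assert "rho_s" in set(frame["parameter"])


class TestPredict:
    def test_conditional_interpolation_at_observed_station(self, gp_panel):
        post = fit_mcmc(gp_panel, n_iter=600, burn_in=200, seed=6)
        i = 4
        pred = predict(post, gp_panel.W[[i]], [gp_panel.states[i]],
                       gp_panel.coords[[i]], new_dates=gp_panel.dates,
                       n_draws=20, seed=1, condition=True)
        # a colocated site reproduces the observed series (Schur -> 0)
        assert np.allclose(pred.mean[0], gp_panel.Y[i], atol=0.05)
        assert np.max(pred.upper[0] - pred.lower[0]) < 0.2

    def test_unconditional_mean_is_linear_predictor(self, gp_panel):
        post = fit_mcmc(gp_panel, n_iter=600, burn_in=200, seed=6)
        W_new = np.tile(np.array([24.2, 240.0, 4.42]), (1, 10, 1))
        coords = np.array([[200.0, 3500.0]])
        pred = predict(post, W_new, [gp_panel.states[0]], coords,
                       new_dates=[str(i) for i in range(10)],
                       n_draws=100, seed=2, condition=False)
        # across many draws the mean field approaches X* beta-bar
        levels = gp_panel.state_levels
        k = levels.index(gp_panel.states[0])
        bbar = post.beta.mean(axis=0)[4 * k:4 * (k + 1)]
        want = bbar @ np.array([1.0, 24.2, 240.0, 4.42])
        mc_sd = np.sqrt(post.sigma2.mean()) / np.sqrt(100)
        assert np.abs(pred.mean.mean() - want) < 4 * mc_sd + 0.5

    def test_dimension_mismatch_errors(self, gp_panel):
        post = fit_mcmc(gp_panel, n_iter=120, burn_in=20, seed=3)
        with pytest.raises(ValueError):
            predict(post, np.zeros((2, 5, 3)), ["ST1", "ST1"],
                    np.zeros((3, 2)), n_draws=10, seed=0, condition=False)


class TestHoldout:
    def test_seeded_holdout_reproducible(self, gp_panel):
        a = validate_holdout(gp_panel, n_holdout=3, seed=4, n_iter=400,
                             burn_in=100, n_draws=30)
        b = validate_holdout(gp_panel, n_holdout=3, seed=4, n_iter=400,
                             burn_in=100, n_draws=30)
        assert a == b

    def test_rmse_and_coverage_in_plausible_range(self, gp_panel):
        rmse, cover = validate_holdout(gp_panel, n_holdout=3, seed=7,
                                       n_iter=1200, burn_in=400, n_draws=80)
        # residual sd is 10.5 ppb; kriging conditioned on 12 neighbours
        # should do clearly better than ignoring space-time structure
        assert 2.0 < rmse < 12.0
        assert 0.85 <= cover <= 1.0

    def test_too_many_holdout_errors(self, gp_panel):
        with pytest.raises(ValueError):
            validate_holdout(gp_panel, n_holdout=15, seed=0)


def test_panel_csv_roundtrip(tmp_path, gp_panel):
    from ozoneimpact.spacetime import read_panel, write_panel
    path = tmp_path / "panel.csv"
    write_panel(gp_panel, path)
    back = read_panel(path)
    assert np.allclose(back.Y, gp_panel.Y)
    assert np.allclose(back.coords, gp_panel.coords)
    assert list(back.states) == list(gp_panel.states)
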