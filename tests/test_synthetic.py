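"""Synthetic-data generators: determinism, contracts, and statistical shape."""

import numpy as np
import pandas as pd
import pytest

from ozoneimpact import exposure, synthetic


class TestNetwork:
    def test_deterministic_under_seed(self):
        a = synthetic.generate_network(10, 2, seed=7)
        b = synthetic.generate_network(10, 2, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seeds_differ(self):
        a, _ = synthetic.generate_network(10, 2, seed=7)
        b, _ = synthetic.generate_network(10, 2, seed=8)
        assert not np.allclose(a["latitude"], b["latitude"])

    def test_communities_disjoint_each_with_station(self):
        stations, comms = synthetic.generate_network(20, 3, seed=1)
        members = synthetic.stations_in_community(stations, comms)
        assert len(members) == 3
        for sids in members.values():
            assert len(sids) >= 1
        # disjoint circles: pairwise centre distance > 2 * radius is not
        # required, but > radius-sum guarantee comes from construction
        x, y = exposure.project_coords(comms["center_lat"],
                                       comms["center_lon"])
        r = comms["radius_km"].to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                d = np.hypot(x[i] - x[j], y[i] - y[j])
                assert d > r[i] + r[j]

    def test_degenerate_bbox_errors(self):
        with pytest.raises(ValueError):
            synthetic.generate_network(5, 1, bbox=(30, 30, -90, -80), seed=0)


class TestWeather:
    def test_zero_noise_gives_seasonal_mean_surface(self):
        stations, _ = synthetic.generate_network(5, 1, seed=3)
        cfg = synthetic.WeatherConfig(
            sds={"temperature": 0.0, "ghi": 0.0, "cloud_cover": 0.0})
        dates = exposure.summer_dates(2000)[:20]
        w = synthetic.generate_weather(stations, dates, seed=3, config=cfg)
        temp = w["temperature"].pivot(index="station_id", columns="date",
                                      values="value")
        # all stations share the deterministic seasonal curve
        assert np.allclose(temp.to_numpy() - temp.to_numpy()[0], 0.0)
        assert temp.to_numpy().mean() == pytest.approx(24.2, abs=1e-9)

    def test_long_run_mean_near_configured(self):
        stations, _ = synthetic.generate_network(10, 1, seed=4)
        dates = [d for y in (1998, 1999, 2000)
                 for d in exposure.summer_dates(y)]
        w = synthetic.generate_weather(stations, dates, seed=4)
        got = w["temperature"]["value"].mean()
        # sd 3 degC, ~4590 station-days with spatial/temporal correlation
        assert got == pytest.approx(24.2, abs=0.8)

    def test_same_seed_identical(self):
        stations, _ = synthetic.generate_network(4, 1, seed=5)
        dates = exposure.summer_dates(2000)[:10]
        a = synthetic.generate_weather(stations, dates, seed=5)
        b = synthetic.generate_weather(stations, dates, seed=5)
        for var in synthetic.WEATHER_VARIABLES:
            pd.testing.assert_frame_equal(a[var], b[var])

    def test_cloud_cover_nonnegative(self):
        stations, _ = synthetic.generate_network(8, 1, seed=6)
        dates = exposure.summer_dates(2000)
        w = synthetic.generate_weather(stations, dates, seed=6)
        assert (w["cloud_cover"]["value"] >= 0).all()

    def test_out_of_season_dates_error(self):
        stations, _ = synthetic.generate_network(4, 1, seed=5)
        with pytest.raises(ValueError):
            synthetic.generate_weather(stations, ["2000-01-15"], seed=5)


class TestOzone:
    def test_noiseless_limit_exact_linear_surface(self):
        stations, _ = synthetic.generate_network(6, 1, seed=8)
        truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                        seed=8, sigma2=0.0)
        dates = exposure.summer_dates(2000)[:15]
        w = synthetic.generate_weather(stations, dates, seed=8)
        oz = synthetic.generate_ozone(stations, w, truth, seed=8)
        panel = synthetic.assemble_panel(stations, w, oz)
        X = panel.design_tensor()
        resid = panel.Y - X @ truth.beta_flat(panel.state_levels)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_lag1_residual_correlation_matches_decay(self):
        stations, _ = synthetic.generate_network(4, 1, seed=9)
        truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                        seed=9)
        dates = exposure.summer_dates(2000)[:40]
        corrs, var0 = [], []
        for rep in range(30):
            w = synthetic.generate_weather(stations, dates, seed=9)
            oz = synthetic.generate_ozone(stations, w, truth, seed=100 + rep)
            panel = synthetic.assemble_panel(stations, w, oz)
            resid = panel.Y - panel.design_tensor() @ truth.beta_flat(
                panel.state_levels)
            a, b = resid[:, :-1].ravel(), resid[:, 1:].ravel()
            corrs.append(np.corrcoef(a, b)[0, 1])
            var0.append(resid.var())
        want = np.exp(-1.0 / truth.rho_t)
        assert np.mean(corrs) == pytest.approx(want, abs=0.05)
        # variogram at distance zero: marginal variance equals sigma2
        assert np.mean(var0) == pytest.approx(truth.sigma2, rel=0.15)


class TestClimateDistortion:
    @pytest.fixture()
    def setup(self):
        stations, comms = synthetic.generate_network(10, 2, seed=12)
        dates = exposure.summer_dates(2000)[:25]
        w = synthetic.generate_weather(stations, dates, seed=12)
        return stations, comms, w

    def test_identity_bias_equals_gridded_truth(self, setup):
        stations, _, w = setup
        bias = {v: (0.0, 1.0, 0.0) for v in synthetic.WEATHER_VARIABLES}
        grid = synthetic.GridSpec(cell_km=100.0)
        out = synthetic.distort_to_climate_output(w, stations, bias, grid,
                                                  seed=12)
        # each cell carries its nearest station's series exactly
        temp = out[out["variable"] == "temperature"]
        sample = temp.iloc[0]
        truth_vals = w["temperature"]["value"]
        assert np.isin(sample["value"], truth_vals)

    def test_zero_slope_output_uninformative(self, setup):
        stations, _, w = setup
        bias = {v: (5.0, 0.0, 1.0) for v in synthetic.WEATHER_VARIABLES}
        grid = synthetic.GridSpec(cell_km=100.0)
        out = synthetic.distort_to_climate_output(w, stations, bias, grid,
                                                  seed=12)
        temp = out[out["variable"] == "temperature"]
        cell = temp[temp["cell_id"] == temp["cell_id"].iloc[0]]
        merged = pd.merge(cell[["date", "value"]],
                          w["temperature"].groupby("date")["value"].mean()
                          .rename("truth").reset_index(), on="date")
        r2 = np.corrcoef(merged["value"], merged["truth"])[0, 1] ** 2
        assert r2 < 0.2

    def test_paper_regime_r2_is_low(self, setup):
        stations, comms, w = setup
        truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                        seed=12)
        grid = synthetic.GridSpec()
        out = synthetic.distort_to_climate_output(w, stations,
                                                  truth.calib_bias, grid,
                                                  seed=12)
        from ozoneimpact import calibration
        counties = comms.rename(columns={"community_id": "county_id"})
        county_model = calibration.link_grid_to_county(out, counties)
        obs = []
        for var in synthetic.WEATHER_VARIABLES:
            agg = synthetic.community_daily_mean(w[var], stations, comms)
            agg["variable"] = var
            obs.append(agg.rename(columns={"community_id": "county_id"}))
        fits = calibration.calibrate_counties(pd.concat(obs), county_model)
        r2 = {v: [f.r2 for f in fits if f.variable == v]
              for v in synthetic.WEATHER_VARIABLES}
        # low-agreement regime: cloud and GHI nearly uninformative
        assert np.median(r2["temperature"]) < 0.6
        assert np.median(r2["ghi"]) < 0.25
        assert np.median(r2["cloud_cover"]) < 0.15


class TestMortality:
    @pytest.fixture()
    def comm_series(self):
        stations, comms = synthetic.generate_network(6, 2, seed=14)
        dates = exposure.summer_dates(2000)
        w = synthetic.generate_weather(stations, dates, seed=14)
        truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                        seed=14)
        oz = synthetic.generate_ozone(stations, w, truth, seed=14)
        oz_c = synthetic.community_daily_mean(oz, stations, comms)
        t_c = synthetic.community_daily_mean(w["temperature"], stations,
                                             comms)
        return comms, oz_c, t_c, truth

    def test_null_risks_give_iid_poisson(self, comm_series):
        comms, oz_c, t_c, truth = comm_series
        truth_null = synthetic.SyntheticTruth(
            beta_r=truth.beta_r, rr=np.zeros(3),
            baseline_rate=truth.baseline_rate)
        mort = synthetic.generate_mortality(comms, oz_c, t_c, truth_null,
                                            seed=3, confounders=False)
        one = mort.query("community == 'comm00' and age_group == 'under65'")
        lam = (truth.baseline_rate * 768_000.0 * synthetic.AGE_SHARES[0])
        assert one["deaths"].mean() == pytest.approx(lam, rel=0.1)
        # index of dispersion ~ 1 for Poisson
        assert one["deaths"].var() / one["deaths"].mean() == pytest.approx(
            1.0, abs=0.35)

    def test_doubling_baseline_doubles_counts(self, comm_series):
        comms, oz_c, t_c, truth = comm_series
        t2 = synthetic.SyntheticTruth(beta_r=truth.beta_r, rr=truth.rr,
                                      baseline_rate=2 * truth.baseline_rate)
        a = synthetic.generate_mortality(comms, oz_c, t_c, truth, seed=3)
        b = synthetic.generate_mortality(comms, oz_c, t_c, t2, seed=3)
        assert b["deaths"].mean() / a["deaths"].mean() == pytest.approx(
            2.0, rel=0.05)

    def test_deterministic(self, comm_series):
        comms, oz_c, t_c, truth = comm_series
        a = synthetic.generate_mortality(comms, oz_c, t_c, truth, seed=5)
        b = synthetic.generate_mortality(comms, oz_c, t_c, truth, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_baseline_errors(self, comm_series):
        comms, oz_c, t_c, truth = comm_series
        with pytest.raises(ValueError):
            synthetic.SyntheticTruth(beta_r=truth.beta_r,
                                     baseline_rate=-1.0)


def test_truth_file_roundtrip(tmp_path):
    truth = synthetic.default_truth(["ST1", "ST2"], seed=17)
    path = tmp_path / "truth.csv"
    truth.save(path)
    back = synthetic.SyntheticTruth.load(path)
    assert back.sigma2 == truth.sigma2
    assert back.rho_s == truth.rho_s
    assert np.allclose(back.rr, truth.rr)
    for st in truth.beta_r:
        assert np.allclose(back.beta_r[st], truth.beta_r[st])
    assert back.calib_bias == truth.calib_bias
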