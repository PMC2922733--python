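"""Simulate the full synthetic study: monitor network, summer weather,
ozone, gridded climate-model output, and community mortality.

Writes every input the downstream analyses read, plus the ground-truth
parameter file (used only to judge recovery), under results/data/.

Usage: python analysis/01_simulate.py [--seed N] [--results DIR]
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ozoneimpact import exposure, synthetic  # noqa: E402
from ozoneimpact.impact import (PipelineConfig, county_weather_long,  # noqa: E402
                                dates_for_years)
from ozoneimpact.spacetime import write_panel  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    cfg = PipelineConfig(seed=args.seed)
    out = Path(args.results) / "data"
    out.mkdir(parents=True, exist_ok=True)

    stations, communities = synthetic.generate_network(
        cfg.n_stations, cfg.n_communities, cfg.bbox, cfg.seed,
        n_states=cfg.n_states)
    truth = synthetic.default_truth(sorted(stations["state"].unique()),
                                    cfg.seed)
    stations.to_csv(out / "stations.csv", index=False)
    communities.to_csv(out / "communities.csv", index=False)
    truth.save(out / "truth.csv")

    # reference-period weather, ozone and the linked panel
    ref_dates = dates_for_years(cfg.reference_years, cfg.gp_n_days)
    weather = synthetic.generate_weather(stations, ref_dates, cfg.seed)
    ozone = synthetic.generate_ozone(stations, weather, truth, cfg.seed)
    panel = synthetic.assemble_panel(stations, weather, ozone)
    write_panel(panel, out / "linked_panel.csv")

    # gridded climate-model output, reference and future periods
    fut_dates = dates_for_years(cfg.future_years)
    w_fut = synthetic.generate_weather(stations, fut_dates, cfg.seed + 22)
    w_fut["temperature"] = w_fut["temperature"].assign(
        value=w_fut["temperature"]["value"] + cfg.temp_signal_c)
    grid = synthetic.GridSpec(cfg.bbox)
    synthetic.distort_to_climate_output(
        weather, stations, truth.calib_bias, grid, cfg.seed + 23
    ).to_csv(out / "grid_reference.csv", index=False)
    synthetic.distort_to_climate_output(
        w_fut, stations, truth.calib_bias, grid, cfg.seed + 24
    ).to_csv(out / "grid_future.csv", index=False)
    county_weather_long(weather, stations, communities).to_csv(
        out / "observed_county_weather.csv", index=False)

    # health-period community series
    years = range(cfg.health_year_start, cfg.health_year_end + 1)
    h_dates = dates_for_years(years)
    w_h = synthetic.generate_weather(stations, h_dates, cfg.seed + 41)
    oz_h = synthetic.generate_ozone(stations, w_h, truth, cfg.seed + 42)
    oz_c = synthetic.community_daily_mean(oz_h, stations, communities)
    t_c = synthetic.community_daily_mean(w_h["temperature"], stations,
                                         communities)
    mort = synthetic.generate_mortality(communities, oz_c, t_c, truth,
                                        cfg.seed + 43)
    mort.to_csv(out / "mortality.csv", index=False)

    print(f"simulated {cfg.n_stations} stations / {cfg.n_communities} "
          f"communities (seed {cfg.seed})")
    print(f"panel: {panel.n_stations} stations x {panel.n_days} days, "
          f"mean ozone {panel.Y.mean():.1f} ppb")
    print(f"mortality: {len(mort)} rows, "
          f"{mort['deaths'].sum():.0f} total deaths")
    print(f"wrote inputs under {out}")


if __name__ == "__main__":
    main()
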