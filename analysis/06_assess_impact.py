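"""Project reference- and future-period community ozone from the fitted
space-time model with calibrated weather, form the exposure change
Delta_x, and compute attributable deaths per lag configuration.

Reads the outputs of steps 01-05; writes the exposure change, the
impact table and a plain-text run report.

Usage: python analysis/06_assess_impact.py [--seed N] [--results DIR]
       [--years 10] [--draws 100]
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ozoneimpact import exposure, synthetic  # noqa: E402
from ozoneimpact.impact import (attributable_deaths, delta_exposure,  # noqa: E402
                                impacts_to_frame)
from ozoneimpact.spacetime import OzonePosterior, predict, read_panel  # noqa: E402


def weather_tensor(calibrated, community_ids, dates):
    n_c, n_t = len(community_ids), len(dates)
    W = np.empty((n_c, n_t, 3))
    idx = pd.Index(dates)
    for i, comm in enumerate(community_ids):
        for k, var in enumerate(synthetic.WEATHER_VARIABLES):
            sub = calibrated[(calibrated["county_id"] == comm)
                             & (calibrated["variable"] == var)]
            W[i, :, k] = (sub.set_index("date")["value"]
                          .reindex(idx).to_numpy(float))
    if not np.all(np.isfinite(W)):
        raise ValueError("calibrated weather incomplete on the county grid")
    return W


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", default="results")
    ap.add_argument("--years", type=int, default=10)
    ap.add_argument("--draws", type=int, default=100)
    args = ap.parse_args()
    res = Path(args.results)
    data = res / "data"

    panel = read_panel(data / "linked_panel.csv")
    draws_tab = pd.read_csv(res / "ozone_posterior_draws.csv")
    post = OzonePosterior.from_frame(draws_tab, panel)
    communities = pd.read_csv(data / "communities.csv")
    stations = pd.read_csv(data / "stations.csv",
                           dtype={"station_id": str, "state": str})
    cal_ref = pd.read_csv(res / "calibrated_reference_weather.csv")
    cal_fut = pd.read_csv(res / "calibrated_future_weather.csv")
    pooled = pd.read_csv(res / "pooled_risk.csv")
    mortality = pd.read_csv(data / "mortality.csv")

    comm_ids = communities["community_id"].tolist()
    ref_dates = np.sort(cal_ref["date"].unique())
    fut_dates = np.sort(cal_fut["date"].unique())
    W_ref = weather_tensor(cal_ref, comm_ids, ref_dates)
    W_fut = weather_tensor(cal_fut, comm_ids, fut_dates)

    ref_lat0 = float(stations["latitude"].mean())
    cx, cy = exposure.project_coords(communities["center_lat"],
                                     communities["center_lon"],
                                     ref_lat=ref_lat0)
    link = exposure.nearest_link(
        communities.rename(columns={"community_id": "station_id",
                                    "center_lat": "latitude",
                                    "center_lon": "longitude"}), stations)
    state_of = dict(zip(stations["station_id"], stations["state"]))
    comm_states = [state_of[s] for s in link["covariate_station_id"]]

    rng = np.random.default_rng(args.seed + 31)
    idx = rng.choice(post.n_draws, size=args.draws, replace=False)
    condition = np.array_equal(ref_dates, panel.dates)
    pred_ref = predict(post, W_ref, comm_states, np.column_stack([cx, cy]),
                       new_dates=ref_dates, n_draws=args.draws,
                       seed=args.seed + 32, condition=condition,
                       draw_indices=idx, station_ids=comm_ids)
    pred_fut = predict(post, W_fut, comm_states, np.column_stack([cx, cy]),
                       new_dates=fut_dates, n_draws=args.draws,
                       seed=args.seed + 33, condition=False,
                       draw_indices=idx, station_ids=comm_ids)
    dx = delta_exposure(pred_ref.draws, pred_fut.draws, comm_ids)
    print(f"projected ozone change: {dx.dx_mean:+.3f} ppb "
          f"(sd {np.sqrt(dx.dx_var):.3f}); reference mean "
          f"{dx.reference_mean:.1f} ppb, future mean {dx.future_mean:.1f}")

    last_year = max(pd.to_datetime(mortality["date"]).dt.year)
    N = float(mortality.loc[mortality["date"].str.startswith(str(last_year)),
                            "deaths"].sum())
    impacts = {}
    for row in pooled.itertuples(index=False):
        imp = attributable_deaths(row.mu_per_ppb, row.sd ** 2, dx.dx_mean,
                                  dx.dx_var, N, args.years)
        impacts[row.lag_spec] = imp
        print(f"{row.lag_spec:>5}: {imp.M:+8.2f} deaths over {args.years} "
              f"seasons ({imp.ci_low:.2f}, {imp.ci_high:.2f}); "
              f"rate change {imp.pct_rate_increase:+.4f}%")
    impacts_to_frame(impacts).to_csv(res / "impact.csv", index=False)
    with open(res / "exposure_change.json", "w") as fh:
        json.dump({"dx_ppb": dx.dx_mean, "dx_var": dx.dx_var,
                   "reference_mean_ppb": dx.reference_mean,
                   "future_mean_ppb": dx.future_mean,
                   "per_community": dx.per_community,
                   "baseline_deaths": N}, fh, indent=2)
    print(f"baseline reference-year deaths: {N:.0f}; wrote impact table")


if __name__ == "__main__":
    main()
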