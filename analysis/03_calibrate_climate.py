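"""Calibrate gridded climate-model weather against observed county
weather (regression calibration) and write calibrated county-day series
for the reference and future periods.

Usage: python analysis/03_calibrate_climate.py [--results DIR]
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ozoneimpact import calibration  # noqa: E402


def calibrated_long(fits, county_model):
    fit_map = {(f.county_id, f.variable): f for f in fits}
    frames = []
    for (county, var), sub in county_model.groupby(["county_id",
                                                    "variable"]):
        cal = calibration.apply_calibration(fit_map[(county, var)],
                                            sub[["date", "value"]])
        cal.insert(0, "county_id", county)
        cal.insert(2, "variable", var)
        frames.append(cal)
    return pd.concat(frames, ignore_index=True)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    res = Path(args.results)
    data = res / "data"
    counties = pd.read_csv(data / "communities.csv").rename(
        columns={"community_id": "county_id"})
    observed = pd.read_csv(data / "observed_county_weather.csv")
    grid_ref = pd.read_csv(data / "grid_reference.csv")
    grid_fut = pd.read_csv(data / "grid_future.csv")

    mod_ref = calibration.link_grid_to_county(grid_ref, counties)
    mod_fut = calibration.link_grid_to_county(grid_fut, counties)
    fits = calibration.calibrate_counties(observed, mod_ref)
    calibration.fits_to_frame(fits).to_csv(res / "calibration_fits.csv",
                                           index=False)
    calibrated_long(fits, mod_ref).to_csv(
        res / "calibrated_reference_weather.csv", index=False)
    calibrated_long(fits, mod_fut).to_csv(
        res / "calibrated_future_weather.csv", index=False)

    frame = calibration.fits_to_frame(fits)
    med = frame.groupby("variable")["r2"].median()
    print("median observed-vs-model r^2 by variable:")
    for var, r2 in med.items():
        print(f"  {var:>12}: {r2:.3f}")
    slopes = frame.groupby("variable")["slope"].median()
    print("median calibration slopes:",
          {v: round(float(s), 3) for v, s in slopes.items()})
    # near-zero slope means the projection collapses to the reference mean
    weak = frame[np.abs(frame["slope"]) < 0.05]
    if len(weak):
        print(f"{len(weak)} county-variable fits are effectively "
              f"mean-fallbacks (|slope| < 0.05)")


if __name__ == "__main__":
    main()
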