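"""Regression calibration of climate-model weather output.

Climate-model output is treated as an error-prone version of the true
weather; observed reference-period weather is the validation data.  For
each county and variable, observed values are regressed (OLS) on the
date-matched model output, and the fitted value at a future model output
is the calibrated projection.  When the model output carries essentially
no information (zero variance, or a fit that cannot be formed) the slope
collapses to zero and the calibrated projection is the reference-period
observed mean — the behaviour low-agreement variables such as cloud
cover exhibit naturally through a near-zero slope.

Gridded output is linked to counties by treating each cell as a point at
its centre: a county's daily value is the unweighted mean over cells
whose centres fall inside the county circle, or the nearest centre if
none do.  Calibration uncertainty is not propagated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import exposure


@dataclass
class CalibrationFit:
    """Per-county, per-variable linear calibration of model output."""
    county_id: str
    variable: str
    intercept: float
    slope: float
    r2: float
    n_days: int
    reference_mean: float


def fit_calibration(observed: pd.DataFrame, model_output: pd.DataFrame,
                    county_id: str, variable: str) -> CalibrationFit:
    """OLS of observed weather on date-matched climate-model output.

    Both inputs are daily series with (date, value) columns for one
    county and variable.  Requires at least 3 matched pairs.  r^2 is the
    squared sample correlation of the pairs.
    """
    merged = pd.merge(observed[["date", "value"]],
                      model_output[["date", "value"]],
                      on="date", suffixes=("_obs", "_mod")).dropna()
    n = len(merged)
    if n < 3:
        raise ValueError(f"{county_id}/{variable}: need >= 3 matched pairs, "
                         f"got {n}")
    obs = merged["value_obs"].to_numpy(float)
    mod = merged["value_mod"].to_numpy(float)
    ref_mean = float(obs.mean())
    if np.var(mod) == 0:
        return CalibrationFit(county_id, variable, ref_mean, 0.0, 0.0,
                              n, ref_mean)
    fit = stats.linregress(mod, obs)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        return CalibrationFit(county_id, variable, ref_mean, 0.0, 0.0,
                              n, ref_mean)
    r2 = float(fit.rvalue ** 2)
    return CalibrationFit(county_id, variable, intercept, slope, r2,
                          n, ref_mean)


def apply_calibration(fit: CalibrationFit, future_model_output: pd.DataFrame,
                      variable: str | None = None) -> pd.DataFrame:
    """Calibrated projection: fitted value at each future model output.

    Returns a (date, value) series; cloud cover is truncated at zero.
    ``variable`` (or a 'variable' column in the input) must match the
    fit's variable.
    """
    if variable is not None and variable != fit.variable:
        raise ValueError(f"variable mismatch: fit is {fit.variable!r}, "
                         f"input is {variable!r}")
    if "variable" in future_model_output.columns:
        vals = future_model_output["variable"].unique()
        if len(vals) != 1 or vals[0] != fit.variable:
            raise ValueError(f"variable mismatch: fit is {fit.variable!r}, "
                             f"input has {vals}")
    out = future_model_output[["date"]].copy()
    v = fit.intercept + fit.slope * future_model_output["value"].to_numpy(float)
    if fit.variable == "cloud_cover":
        v = np.maximum(v, 0.0)
    out["value"] = v
    return out


def link_grid_to_county(grid_table: pd.DataFrame,
                        county_definitions: pd.DataFrame) -> pd.DataFrame:
    """County-day weather from gridded output.

    Grid cells are points at their centres; a county's value is the
    unweighted mean over centres inside its circle (radius_km around
    center_lat/lon), falling back to the single nearest centre.  Returns
    a long table (county_id, date, variable, value).
    """
    cells = (grid_table.drop_duplicates("cell_id")
             [["cell_id", "center_lat", "center_lon"]]
             .sort_values("cell_id").reset_index(drop=True))
    if len(cells) == 0:
        raise ValueError("empty grid table")
    lat = np.concatenate([cells["center_lat"].to_numpy(float),
                          county_definitions["center_lat"].to_numpy(float)])
    lon = np.concatenate([cells["center_lon"].to_numpy(float),
                          county_definitions["center_lon"].to_numpy(float)])
    x, y = exposure.project_coords(lat, lon)
    nc = len(cells)
    cx, cy = x[:nc], y[:nc]
    frames = []
    for i, county in county_definitions.reset_index(drop=True).iterrows():
        d = np.hypot(cx - x[nc + i], cy - y[nc + i])
        inside = cells["cell_id"].to_numpy()[d <= county["radius_km"]]
        if inside.size == 0:
            inside = np.array([cells["cell_id"].iloc[int(np.argmin(d))]])
        sub = grid_table[grid_table["cell_id"].isin(inside)]
        agg = (sub.groupby(["date", "variable"], sort=True)["value"]
               .mean().reset_index())
        agg.insert(0, "county_id", county["county_id"])
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)


def fits_to_frame(fits) -> pd.DataFrame:
    return pd.DataFrame([{
        "county_id": f.county_id, "variable": f.variable,
        "intercept": f.intercept, "slope": f.slope, "r2": f.r2,
        "n_days": f.n_days, "reference_mean": f.reference_mean,
    } for f in fits])


def calibrate_counties(observed_by_county: pd.DataFrame,
                       model_by_county: pd.DataFrame) -> list:
    """Fit every (county, variable) pair present in both tables.

    Inputs are long tables (county_id, date, variable, value).
    """
    fits = []
    keys = (observed_by_county[["county_id", "variable"]]
            .drop_duplicates().sort_values(["county_id", "variable"]))
    for county, var in keys.itertuples(index=False, name=None):
        obs = observed_by_county.query(
            "county_id == @county and variable == @var")
        mod = model_by_county.query(
            "county_id == @county and variable == @var")
        fits.append(fit_calibration(obs, mod, county, var))
    return fits
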