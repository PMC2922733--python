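"""Exposure metrics and tabular data handling.

Implements the regulatory ozone exposure metrics (MDA8 and the NAAQS
design value), an equirectangular coordinate projection to planar km,
closest-distance linkage of ozone monitors to meteorology stations, and
CSV I/O for the tabular inputs the pipeline consumes.

Conventions
-----------
* Dates are ISO-8601 strings; the summer season is May 1 - September 30.
* Missing values are encoded as empty CSV fields and ``NaN`` in memory.
* MDA8 uses the 17 eight-hour windows fully inside a calendar day
  (start hours 0-16); a window is valid iff at least 6 of its 8 hourly
  values are present (75% completeness), and the window mean uses the
  available values only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

KM_PER_DEG = 111.32

#: first day (inclusive) and last day (inclusive) of the ozone season
SUMMER_START = (5, 1)
SUMMER_END = (9, 30)

STATION_COLUMNS = ["station_id", "latitude", "longitude", "state", "variable"]
HOURLY_COLUMNS = ["station_id", "date", "hour", "o3_ppb"]
DAILY_COLUMNS = ["station_id", "date", "value"]

#: minimum present hours for a valid 8-hour window: ceil(0.75 * 8)
MIN_HOURS_PER_WINDOW = 6
N_WINDOWS = 17  # start hours 0..16

NAAQS_THRESHOLD_PPB = 75.0


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def project_coords(latitudes, longitudes, ref_lat: float | None = None):
    """Project lat/lon (decimal degrees) to planar (x, y) kilometers.

    Equirectangular projection about the centroid latitude of the input
    set: ``y = 111.32 * lat`` and ``x = 111.32 * lon * cos(lat_centroid)``.
    Euclidean distance on the result approximates great-circle distance
    at a regional scale.

    Parameters
    ----------
    latitudes, longitudes : array-like of float
        Coordinates in decimal degrees.
    ref_lat : float, optional
        Reference latitude for the cosine scaling; pass the centroid of
        another point set to place these points in its planar frame.
        Defaults to the centroid of the input.

    Returns
    -------
    (x_km, y_km) : tuple of ndarray
    """
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    if lat.size == 0:
        raise ValueError("project_coords requires at least one coordinate")
    if lat.shape != lon.shape:
        raise ValueError("latitude and longitude arrays must have equal shape")
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude out of [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValueError("longitude out of [-180, 180]")
    lat0 = np.mean(lat) if ref_lat is None else float(ref_lat)
    x = KM_PER_DEG * lon * np.cos(np.deg2rad(lat0))
    y = KM_PER_DEG * lat
    return x, y


def nearest_link(ozone_stations: pd.DataFrame,
                 covariate_stations: pd.DataFrame) -> pd.DataFrame:
    """Map each ozone monitor to its closest covariate station.

    Distances are Euclidean in the plane after a joint equirectangular
    projection of both station sets. Ties are broken by the
    lexicographically smallest covariate ``station_id`` so the linkage
    is deterministic and invariant to row order.

    Returns
    -------
    DataFrame with columns ``ozone_station_id``, ``covariate_station_id``,
    ``distance_km``, one row per ozone station.
    """
    if len(ozone_stations) == 0 or len(covariate_stations) == 0:
        raise ValueError("nearest_link requires non-empty station tables")
    oz = ozone_stations.sort_values("station_id").reset_index(drop=True)
    cv = covariate_stations.sort_values("station_id").reset_index(drop=True)
    all_lat = np.concatenate([oz["latitude"].to_numpy(float),
                              cv["latitude"].to_numpy(float)])
    all_lon = np.concatenate([oz["longitude"].to_numpy(float),
                              cv["longitude"].to_numpy(float)])
    x, y = project_coords(all_lat, all_lon)
    n_oz = len(oz)
    ox, oy = x[:n_oz], y[:n_oz]
    cx, cy = x[n_oz:], y[n_oz:]
    d = np.hypot(ox[:, None] - cx[None, :], oy[:, None] - cy[None, :])
    # argmin returns the first minimum; cv is sorted by station_id, so the
    # tie-break to the smallest id is automatic
    j = np.argmin(d, axis=1)
    return pd.DataFrame({
        "ozone_station_id": oz["station_id"].to_numpy(),
        "covariate_station_id": cv["station_id"].to_numpy()[j],
        "distance_km": d[np.arange(n_oz), j],
    })


# ---------------------------------------------------------------------------
# ozone metrics
# ---------------------------------------------------------------------------

def compute_mda8(hours, concentrations) -> float:
    """Maximum daily 8-hour average ozone for one station-day.

    Scans the 17 windows starting at hours 0-16. A window is valid iff
    at least 6 of its 8 hourly values are present; a valid window's mean
    uses available values only. Returns the maximum over valid window
    means, or NaN if no window is valid.

    Parameters
    ----------
    hours : array-like of int
        Hour of each measurement, 0-23.
    concentrations : array-like of float
        Hourly concentrations in ppb; NaN marks a missing hour.
    """
    hours = np.asarray(hours, dtype=int)
    conc = np.asarray(concentrations, dtype=float)
    if hours.size and (hours.min() < 0 or hours.max() > 23):
        raise ValueError("hour outside 0-23")
    if np.any(conc[np.isfinite(conc)] < 0):
        raise ValueError("negative ozone concentration")
    day = np.full(24, np.nan)
    day[hours] = conc
    best = np.nan
    for start in range(N_WINDOWS):
        window = day[start:start + 8]
        present = np.isfinite(window)
        if present.sum() >= MIN_HOURS_PER_WINDOW:
            m = window[present].mean()
            if not np.isfinite(best) or m > best:
                best = m
    return best


def daily_mda8(hourly: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`compute_mda8` to every (station, date) in an hourly table.

    Returns a daily series DataFrame (station_id, date, value).
    """
    rows = []
    for (sid, date), grp in hourly.groupby(["station_id", "date"], sort=True):
        rows.append((sid, date,
                     compute_mda8(grp["hour"].to_numpy(),
                                  grp["o3_ppb"].to_numpy())))
    return pd.DataFrame(rows, columns=DAILY_COLUMNS)


def design_value(yearly_mda8: dict) -> tuple[float, float]:
    """NAAQS ozone design value for one monitor.

    Parameters
    ----------
    yearly_mda8 : mapping of year -> array-like of daily MDA8 (ppb)
        Three consecutive years of daily MDA8 values; NaNs allowed.

    Returns
    -------
    (design_value_ppb, threshold_ppb)
        The 3-year mean of each year's fourth-highest daily MDA8, and
        the 75 ppb attainment threshold it is compared against.
    """
    if len(yearly_mda8) != 3:
        raise ValueError("design_value requires exactly 3 years")
    fourth_highest = []
    for year, values in yearly_mda8.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 4:
            raise ValueError(f"year {year}: fewer than 4 valid daily values")
        fourth_highest.append(np.sort(v)[::-1][3])
    return float(np.mean(fourth_highest)), NAAQS_THRESHOLD_PPB


# ---------------------------------------------------------------------------
# season helpers
# ---------------------------------------------------------------------------

def in_summer(dates) -> np.ndarray:
    """Boolean mask for dates within the May 1 - September 30 season."""
    d = pd.to_datetime(pd.Series(dates))
    md = list(zip(d.dt.month, d.dt.day))
    return np.array([SUMMER_START <= x <= SUMMER_END for x in md])


def summer_dates(year: int) -> list[str]:
    """All ISO dates of one May-September season."""
    idx = pd.date_range(f"{year}-{SUMMER_START[0]:02d}-{SUMMER_START[1]:02d}",
                        f"{year}-{SUMMER_END[0]:02d}-{SUMMER_END[1]:02d}")
    return [d.strftime("%Y-%m-%d") for d in idx]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str, "state": str})
    _require(df, STATION_COLUMNS, path)
    return df


def read_hourly_ozone(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str, "date": str})
    _require(df, HOURLY_COLUMNS, path)
    return df


def read_daily_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str, "date": str})
    _require(df, DAILY_COLUMNS, path)
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
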