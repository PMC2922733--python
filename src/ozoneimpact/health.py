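"""Community time-series models of daily mortality and ozone.

For each community, daily non-accidental death counts by age stratum are
regressed on lagged ozone via quasi-Poisson (Poisson with over-dispersion):

    log E[y_t] = beta * x_t + gamma' Z_t

where x_t is community-average MDA8 ozone (single lag 0/1/2, or three
simultaneous lags for the unconstrained distributed-lag model) and Z_t
holds the confounders: day-of-week and age-stratum baseline indicators,
age-by-trend interactions, and natural cubic splines of long-term trend,
same-day and previous-three-day mean temperature and dew point.  The
cumulative distributed-lag effect is the sum of the three lag
coefficients, with variance summing the full 3x3 covariance block.

Summers are disjoint time blocks: exposure lags and running means never
cross the gap between seasons, so the leading days of each summer are
dropped from the design.  Coefficients are stored per ppb; summaries
report percent change per 10 ppb as 100*(exp(10*beta)-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

LAG_SPECS = ("lag0", "lag1", "lag2", "dl02")
SERIES_COLUMNS = ["community", "date", "age_group", "deaths", "o3_mda8",
                  "temp_c", "dewpt_c"]


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------

def ns_basis(x, df: int, boundary: tuple | None = None) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Interior knots sit at equally spaced quantiles of ``x``; boundary
    knots at the min/max (or at ``boundary``).  The fitted function is
    linear beyond the boundary knots (second derivative zero), the
    defining constraint of a natural spline.  ``df=1`` reduces to a
    single linear column.

    Uses the truncated-power natural-spline construction: with knots
    xi_1 < ... < xi_K, the basis is {x, d_k(x) - d_{K-1}(x)} for
    k = 1..K-2, where d_k(x) = [(x-xi_k)_+^3 - (x-xi_K)_+^3]/(xi_K-xi_k).
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    distinct = np.unique(x)
    if distinct.size < df + 2:
        raise ValueError(f"need at least {df + 2} distinct values for df={df}")
    if boundary is None:
        lo, hi = distinct[0], distinct[-1]
    else:
        lo, hi = boundary
    if df == 1:
        return x[:, None].copy()
    interior = np.quantile(distinct, np.linspace(0, 1, df + 1)[1:-1])
    knots = np.concatenate([[lo], interior, [hi]])
    # affine rescale to [0, 1]: leaves the spanned space unchanged but
    # keeps the cubic terms well conditioned for wide inputs (day indices)
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate boundary knots")
    x = (x - lo) / span
    knots = (knots - lo) / span
    K = len(knots)

    def d(k_idx, t):
        num = (np.maximum(t - knots[k_idx], 0.0) ** 3
               - np.maximum(t - knots[K - 1], 0.0) ** 3)
        return num / (knots[K - 1] - knots[k_idx])

    cols = [x]
    dK1 = d(K - 2, x)
    for k in range(K - 2):
        cols.append(d(k, x) - dK1)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class ConfounderSpec:
    """Degrees of freedom and indicator sets for the confounder block Z.

    Spline dfs follow multi-site mortality time-series convention,
    reduced pro rata for summer-only series: long-term trend 3 df per
    summer, temperature 6 df (same-day and previous-three-day mean),
    dew point 3 df each.  All configurable; ``trend_df_per_summer`` is
    the usual sensitivity dial for confounding by season.
    """
    trend_df_per_summer: int = 3
    temp_df: int = 6
    temp_runmean_df: int = 6
    dew_df: int = 3
    dew_runmean_df: int = 3
    day_of_week: bool = True
    age_strata: bool = True
    age_trend_interaction: bool = True


@dataclass
class Design:
    """Materialised regression design for one community."""
    X: pd.DataFrame                  # n_rows x n_cols, named columns
    y: np.ndarray                    # death counts
    ozone_columns: list              # names of the exposure column(s)
    community_id: str
    lag_spec: str
    n_days: int                      # distinct days retained
    n_dropped_days: int


def _within_summer_lag(x: np.ndarray, years: np.ndarray, lag: int
                       ) -> np.ndarray:
    """Shift a day-level series by ``lag`` days without crossing summers."""
    out = np.full_like(x, np.nan, dtype=float)
    for yr in np.unique(years):
        ix = np.where(years == yr)[0]
        if lag < len(ix):
            out[ix[lag:]] = x[ix[:len(ix) - lag]]
    return out


def _prev3_mean(x: np.ndarray, years: np.ndarray) -> np.ndarray:
    lags = [_within_summer_lag(x, years, k) for k in (1, 2, 3)]
    return np.mean(lags, axis=0)


def build_design(series: pd.DataFrame, lag_spec: str,
                 conf: ConfounderSpec | None = None) -> Design:
    """Build the quasi-Poisson design for one community.

    ``series`` is the long CommunitySeries table for a single community
    (one row per date and age stratum).  Rows whose exposure lags or
    running-mean weather are incomputable (the first days of each
    summer) or whose covariates are missing are dropped and counted.
    """
    if conf is None:
        conf = ConfounderSpec()
    if lag_spec not in LAG_SPECS:
        raise ValueError(f"lag_spec must be one of {LAG_SPECS}")
    comm = series["community"].unique()
    if len(comm) != 1:
        raise ValueError("build_design expects a single community")
    daily = (series.drop_duplicates("date")
             .sort_values("date").reset_index(drop=True))
    dates = pd.to_datetime(daily["date"])
    years = dates.dt.year.to_numpy()
    x = daily["o3_mda8"].to_numpy(float)
    temp = daily["temp_c"].to_numpy(float)
    dew = daily["dewpt_c"].to_numpy(float)

    lags = {k: _within_summer_lag(x, years, k) for k in range(3)}
    temp_rm = _prev3_mean(temp, years)
    dew_rm = _prev3_mean(dew, years)
    if lag_spec == "dl02":
        oz = {f"o3_lag{k}": lags[k] for k in range(3)}
    else:
        k = int(lag_spec[-1])
        oz = {f"o3_lag{k}": lags[k]}

    day_cols = {**oz, "temp": temp, "temp_rm": temp_rm,
                "dew": dew, "dew_rm": dew_rm}
    keep = np.all(np.isfinite(np.column_stack(list(day_cols.values()))),
                  axis=1)
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no usable days after dropping incomputable rows")
    kept_dates = daily["date"].to_numpy()[keep]

    # day-level confounder splines evaluated on retained days
    n_summers = len(np.unique(years))
    t_index = (dates - dates.iloc[0]).dt.days.to_numpy(float)[keep]
    blocks = {}
    trend_df = conf.trend_df_per_summer * n_summers
    trend = ns_basis(t_index, trend_df)
    for j in range(trend.shape[1]):
        blocks[f"trend{j + 1}"] = trend[:, j]
    for name, v, dfv in (("temp", temp, conf.temp_df),
                         ("temp_rm", temp_rm, conf.temp_runmean_df),
                         ("dew", dew, conf.dew_df),
                         ("dew_rm", dew_rm, conf.dew_runmean_df)):
        B = ns_basis(v[keep], dfv)
        for j in range(B.shape[1]):
            blocks[f"{name}_s{j + 1}"] = B[:, j]
    for name in oz:
        blocks[name] = oz[name][keep]
    dow = dates.dt.dayofweek.to_numpy()[keep]

    day_frame = pd.DataFrame(blocks, index=kept_dates)
    day_frame["dow"] = dow

    # stack age strata
    sub = series[series["date"].isin(kept_dates)].copy()
    sub = sub.sort_values(["age_group", "date"]).reset_index(drop=True)
    ages = sorted(sub["age_group"].unique())
    X_parts = {}
    stacked = day_frame.loc[sub["date"].to_numpy()]
    for name in day_frame.columns:
        if name == "dow":
            continue
        X_parts[name] = stacked[name].to_numpy()
    if conf.day_of_week:
        for k in range(1, 7):
            X_parts[f"dow{k}"] = (stacked["dow"].to_numpy() == k).astype(float)
    if conf.age_strata:
        for a in ages:
            X_parts[f"age_{a}"] = (sub["age_group"] == a).to_numpy(float)
    else:
        X_parts["intercept"] = np.ones(len(sub))
    if conf.age_trend_interaction and len(ages) > 1:
        for a in ages[1:]:
            ind = (sub["age_group"] == a).to_numpy(float)
            for j in range(trend.shape[1]):
                X_parts[f"age_{a}:trend{j + 1}"] = ind * stacked[
                    f"trend{j + 1}"].to_numpy()
    X = pd.DataFrame(X_parts)
    y = sub["deaths"].to_numpy(float)
    return Design(X, y, list(oz.keys()), str(comm[0]), lag_spec,
                  int(keep.sum()), n_dropped)


# ---------------------------------------------------------------------------
# quasi-Poisson fit
# ---------------------------------------------------------------------------

@dataclass
class RiskEstimate:
    """Community-specific ozone-mortality coefficient.

    beta_hat is the log rate change per ppb; var_hat its estimation
    variance (dispersion-scaled); for the distributed-lag model the
    per-lag coefficients and covariance block are retained.
    """
    community_id: str
    lag_spec: str
    beta_hat: float
    var_hat: float
    dispersion: float
    n_days: int
    lag_coef: np.ndarray | None = None
    lag_cov: np.ndarray | None = None

    @property
    def pct_per_10ppb(self) -> float:
        return 100.0 * (np.exp(10.0 * self.beta_hat) - 1.0)


def fit_quasi_poisson(design: Design, max_iter: int = 100) -> RiskEstimate:
    """Fit the community model by IRLS and extract the ozone effect.

    Over-dispersion is estimated as Pearson chi^2 / residual df and
    scales the coefficient covariance.  Aliased (linearly dependent)
    columns are dropped with a warning before fitting.  For the
    distributed-lag design the returned estimate is the cumulative
    effect (sum of lag coefficients, variance from the covariance block).
    """
    if np.all(design.y == 0):
        raise ValueError("all death counts are zero")
    X = design.X
    # drop aliased columns via pivoted QR on the standardized design
    q = np.linalg.qr(X.to_numpy(), mode="r")
    diag = np.abs(np.diag(q))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if np.any(diag < tol):
        keep_idx = _independent_columns(X.to_numpy())
        dropped = [c for i, c in enumerate(X.columns) if i not in keep_idx]
        warnings.warn(f"dropping aliased design columns: {dropped}")
        X = X.iloc[:, sorted(keep_idx)]
        if any(c in dropped for c in design.ozone_columns):
            raise ValueError("ozone column aliased with confounders")
    # fit on a column-rescaled design (exact reparameterisation) so IRLS
    # converges despite the wide range of column magnitudes
    scales = np.abs(X.to_numpy()).max(axis=0)
    scales[scales == 0] = 1.0
    Xs = X / scales
    model = sm.GLM(design.y, Xs, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=max_iter, tol=1e-6)
    if not res.converged:
        # statsmodels' criterion is an absolute deviance change (1e-8),
        # unreachable at double precision for deviances in the thousands;
        # accept a relative change at the precision floor instead
        dev = res.fit_history["deviance"]
        if len(dev) < 2 or abs(dev[-1] - dev[-2]) > 1e-9 * max(1.0, abs(dev[-1])):
            raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")
    disp = float(res.scale)
    cov = res.cov_params() / np.outer(scales, scales)
    res_params = res.params / scales
    if design.lag_spec == "dl02":
        coef = res_params[design.ozone_columns].to_numpy()
        block = cov.loc[design.ozone_columns, design.ozone_columns].to_numpy()
        beta, var = distributed_lag_cumulative(coef, block)
        return RiskEstimate(design.community_id, design.lag_spec, beta, var,
                            disp, design.n_days, coef, block)
    col = design.ozone_columns[0]
    return RiskEstimate(design.community_id, design.lag_spec,
                        float(res_params[col]), float(cov.loc[col, col]),
                        disp, design.n_days)


def _independent_columns(A: np.ndarray) -> set:
    """Greedy left-to-right selection of a full-rank column subset."""
    keep: list = []
    for j in range(A.shape[1]):
        trial = A[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return set(keep)


def distributed_lag_cumulative(coef_vector, cov_block) -> tuple[float, float]:
    """Cumulative distributed-lag effect and its variance.

    The overall effect across lags 0-2 is the sum of the coefficients;
    its variance sums all entries of the covariance block (accounting
    for the correlation between lagged exposures).
    """
    coef = np.asarray(coef_vector, dtype=float)
    cov = np.asarray(cov_block, dtype=float)
    if coef.shape != (3,) or cov.shape != (3, 3):
        raise ValueError("expected 3 lag coefficients with 3x3 covariance")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-12):
        raise ValueError("covariance block is not symmetric")
    return float(coef.sum()), float(cov.sum())


def fit_community(series: pd.DataFrame, lag_spec: str,
                  conf: ConfounderSpec | None = None) -> RiskEstimate:
    """Convenience wrapper: build the design and fit one community."""
    return fit_quasi_poisson(build_design(series, lag_spec, conf))


def fit_all_communities(series: pd.DataFrame, lag_spec: str,
                        conf: ConfounderSpec | None = None) -> list:
    """Fit every community in a multi-community series table."""
    return [fit_community(series[series["community"] == c], lag_spec, conf)
            for c in sorted(series["community"].unique())]


def estimates_to_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame([{
        "community": e.community_id, "lag_spec": e.lag_spec,
        "beta_per_ppb": e.beta_hat, "var": e.var_hat,
        "dispersion": e.dispersion, "n": e.n_days,
        "pct_per_10ppb": e.pct_per_10ppb,
    } for e in estimates])


def read_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"community": str, "date": str,
                                  "age_group": str})
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
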