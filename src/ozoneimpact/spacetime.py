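"""Bayesian space-time model for daily summer ozone.

Daily maximum 8-hour ozone at monitor s on day t is modelled as a linear
function of weather with state-specific coefficients,

    Y(s,t) = X(s,t) beta_r + e(s,t),

where X collects an intercept, mean temperature (degC), solar radiation
(GHI, W/m2) and total cloud cover (%), and the residual field e is a
mean-zero Gaussian process with a separable exponential covariance

    Cov[e(s1,t1), e(s2,t2)] = sigma2 * exp(-||s1-s2||/rho_s) * exp(-|t1-t2|/rho_t)

with distance in km after planar projection and time in days.  Inference
is by MCMC: conjugate Gibbs updates for the regression coefficients
(normal) and residual variance (inverse-gamma), and a random-walk
Metropolis step on (log rho_s, log rho_t) with reflection at the bounds
of their uniform priors.  For complete station-by-day panels the
likelihood uses the Kronecker factorization of the space-time correlation
(cost O(n_s^3 + n_t^3) per evaluation); incomplete panels fall back to a
dense covariance restricted to the observed entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

COEF_NAMES = ["intercept", "temp_c", "ghi_wm2", "cloud_pct"]
N_COEF = len(COEF_NAMES)

#: correlation level defining the effective range of an exponential
#: correlation function (reached at separation 3*rho since exp(-3)~0.0498)
EFFECTIVE_RANGE_LEVEL = 0.05

PANEL_COLUMNS = ["station_id", "date", "o3_mda8", "temp_c", "ghi_wm2",
                 "cloud_pct", "state", "x_km", "y_km"]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STCovarianceParams:
    """Separable exponential covariance parameters.

    sigma2 : residual variance, ppb^2
    rho_s  : spatial decay scale, km
    rho_t  : temporal decay scale, days
    """
    sigma2: float
    rho_s: float
    rho_t: float

    def __post_init__(self):
        if not (self.sigma2 > 0 and self.rho_s > 0 and self.rho_t > 0):
            raise ValueError("covariance parameters must be strictly positive")


@dataclass
class GPPriors:
    """Prior specification for the space-time ozone model.

    rho_s ~ Uniform(10, 350) km (effective range 30-1050 km);
    rho_t ~ Uniform(0, 5) days (effective range 0-15 days);
    sigma2 ~ InverseGamma(0.01, 0.01); beta ~ N(0, 1e8 I) (proper, flat).
    """
    rho_s_range: tuple = (10.0, 350.0)
    rho_t_range: tuple = (0.0, 5.0)
    sigma2_shape: float = 0.01
    sigma2_rate: float = 0.01
    beta_precision: float = 1e-8


def residual_correlation(params: STCovarianceParams, d_km, d_days):
    """Residual correlation at spatial lag ``d_km`` and temporal lag ``d_days``.

    Separable product exp(-d_km/rho_s) * exp(-d_days/rho_t); equals 1 at
    zero separation.
    """
    d_km = np.asarray(d_km, dtype=float)
    d_days = np.asarray(d_days, dtype=float)
    if np.any(d_km < 0) or np.any(d_days < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-d_km / params.rho_s) * np.exp(-d_days / params.rho_t)
    return out if out.ndim else float(out)


def effective_range(rho: float) -> float:
    """Separation at which the exponential correlation drops to 0.05.

    With corr(d) = exp(-d/rho) this is -log(0.05)*rho ~ 3*rho; the
    conventional 3*rho is returned.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    return 3.0 * rho


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------

@dataclass
class LinkedPanel:
    """Monitor-by-day ozone responses joined to nearest-station weather.

    Y is (n_s, n_t) with NaN for missing responses; W is (n_s, n_t, 3)
    holding (temp_c, ghi_wm2, cloud_pct); coords are planar km.
    """
    station_ids: np.ndarray          # (n_s,)
    coords: np.ndarray               # (n_s, 2) km
    states: np.ndarray               # (n_s,) state labels
    dates: np.ndarray                # (n_t,) ISO date strings
    day_index: np.ndarray            # (n_t,) integer day offsets
    Y: np.ndarray                    # (n_s, n_t)
    W: np.ndarray                    # (n_s, n_t, 3)

    @property
    def n_stations(self) -> int:
        return len(self.station_ids)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    @property
    def state_levels(self) -> list:
        return sorted(set(self.states.tolist()))

    @property
    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.Y)))

    def design_tensor(self) -> np.ndarray:
        """State-blocked design (n_s, n_t, p) with p = 4 * n_states.

        Station rows are nonzero only in their own state's 4-column block
        (intercept, temp, GHI, cloud), giving state-specific coefficients
        estimated jointly under the shared covariance.
        """
        levels = self.state_levels
        n_s, n_t = self.Y.shape
        X = np.zeros((n_s, n_t, N_COEF * len(levels)))
        base = np.concatenate(
            [np.ones((n_s, n_t, 1)), self.W], axis=2)  # (n_s, n_t, 4)
        for i, st in enumerate(self.states):
            k = levels.index(st)
            X[i, :, k * N_COEF:(k + 1) * N_COEF] = base[i]
        return X

    def coef_names(self) -> list:
        return [f"{st}:{c}" for st in self.state_levels for c in COEF_NAMES]

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def lag_matrix(self) -> np.ndarray:
        t = self.day_index.astype(float)
        return np.abs(t[:, None] - t[None, :])

    def subset_stations(self, keep: np.ndarray) -> "LinkedPanel":
        return LinkedPanel(self.station_ids[keep], self.coords[keep],
                           self.states[keep], self.dates, self.day_index,
                           self.Y[keep], self.W[keep])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LinkedPanel":
        """Build from the long CSV schema (one row per station-day)."""
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        stations = df.drop_duplicates("station_id").sort_values("station_id")
        sid = stations["station_id"].to_numpy()
        coords = stations[["x_km", "y_km"]].to_numpy(float)
        states = stations["state"].to_numpy()
        dates = np.sort(df["date"].unique())
        day_index = (pd.to_datetime(dates) -
                     pd.to_datetime(dates[0])).days.to_numpy()
        si = {s: i for i, s in enumerate(sid)}
        ti = {d: j for j, d in enumerate(dates)}
        n_s, n_t = len(sid), len(dates)
        Y = np.full((n_s, n_t), np.nan)
        W = np.full((n_s, n_t, 3), np.nan)
        rows = df["station_id"].map(si).to_numpy()
        cols = df["date"].map(ti).to_numpy()
        Y[rows, cols] = df["o3_mda8"].to_numpy(float)
        W[rows, cols] = df[["temp_c", "ghi_wm2", "cloud_pct"]].to_numpy(float)
        return cls(sid, coords, states, dates, day_index, Y, W)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, s in enumerate(self.station_ids):
            for j, d in enumerate(self.dates):
                recs.append((s, d, self.Y[i, j], *self.W[i, j],
                             self.states[i], *self.coords[i]))
        return pd.DataFrame(recs, columns=PANEL_COLUMNS)


def read_panel(path) -> LinkedPanel:
    return LinkedPanel.from_dataframe(
        pd.read_csv(path, dtype={"station_id": str, "date": str,
                                 "state": str}))


def write_panel(panel: LinkedPanel, path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# likelihood engines
# ---------------------------------------------------------------------------

def _corr_eig(D: np.ndarray, rho: float):
    """Eigendecomposition of exp(-D/rho) with a one-shot jitter retry."""
    R = np.exp(-D / rho)
    lam, U = np.linalg.eigh(R)
    if lam.min() <= 1e-12:
        R = R + 1e-8 * np.eye(len(R))
        lam, U = np.linalg.eigh(R)
        if lam.min() <= 0:
            raise np.linalg.LinAlgError(
                "correlation matrix not positive definite even after 1e-8 "
                "jitter; increase rho or add diagonal jitter")
    return lam, U


class _KroneckerEngine:
    """Whitening engine for complete panels: R = R_s (x) R_t.

    Whitened quantities are on the correlation scale (sigma2 excluded),
    so quadratic forms divide by sigma2 and logdet adds n*log(sigma2).
    """

    def __init__(self, panel: LinkedPanel):
        self.Ds = panel.distance_matrix()
        self.Dt = panel.lag_matrix()
        self.Ymat = panel.Y
        self.Xt = panel.design_tensor()       # (n_s, n_t, p)
        self.n_s, self.n_t, self.p = self.Xt.shape
        self.n = self.n_s * self.n_t

    def decompose(self, rho_s, rho_t):
        lam_s, U_s = _corr_eig(self.Ds, rho_s)
        lam_t, U_t = _corr_eig(self.Dt, rho_t)
        logdet = self.n_t * np.log(lam_s).sum() + self.n_s * np.log(lam_t).sum()
        return (lam_s, U_s, lam_t, U_t), logdet

    def whiten_field(self, dec, V):
        lam_s, U_s, lam_t, U_t = dec
        return (U_s.T @ V @ U_t) / np.sqrt(np.outer(lam_s, lam_t))

    def whiten_design(self, dec):
        Wx = np.empty((self.n, self.p))
        for k in range(self.p):
            Wx[:, k] = self.whiten_field(dec, self.Xt[..., k]).ravel()
        return Wx

    def whiten_response(self, dec):
        return self.whiten_field(dec, self.Ymat).ravel()

    def whiten_resid(self, dec, beta):
        resid = self.Ymat - self.Xt @ beta
        return self.whiten_field(dec, resid).ravel()


class _DenseEngine:
    """Whitening engine for incomplete panels (observed entries only)."""

    def __init__(self, panel: LinkedPanel):
        obs = np.isfinite(panel.Y)
        si, ti = np.where(obs)
        coords = panel.coords[si]
        times = panel.day_index[ti].astype(float)
        d = coords[:, None, :] - coords[None, :, :]
        self.Ds = np.sqrt((d ** 2).sum(-1))
        self.Dt = np.abs(times[:, None] - times[None, :])
        self.y = panel.Y[si, ti]
        self.X = panel.design_tensor()[si, ti, :]
        self.n, self.p = self.X.shape

    def decompose(self, rho_s, rho_t):
        R = np.exp(-self.Ds / rho_s - self.Dt / rho_t)
        try:
            L = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            try:
                L = np.linalg.cholesky(R + 1e-8 * np.eye(self.n))
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    "dense correlation not positive definite after 1e-8 "
                    "jitter") from err
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return L, logdet

    def whiten_design(self, L):
        return solve_triangular(L, self.X, lower=True)

    def whiten_response(self, L):
        return solve_triangular(L, self.y, lower=True)

    def whiten_resid(self, L, beta):
        return solve_triangular(L, self.y - self.X @ beta, lower=True)


def _make_engine(panel: LinkedPanel):
    if not np.any(np.isfinite(panel.Y)):
        raise ValueError("panel response is entirely missing")
    if not np.all(np.isfinite(panel.W[np.isfinite(panel.Y)])):
        raise ValueError("covariates must be finite where the response is present")
    return _KroneckerEngine(panel) if panel.is_complete else _DenseEngine(panel)


def log_likelihood(panel: LinkedPanel, beta_r: np.ndarray,
                   params: STCovarianceParams) -> float:
    """Gaussian-process log likelihood of the panel residuals.

    ``beta_r`` is the flat coefficient vector ordered by sorted state then
    (intercept, temp, GHI, cloud).  Complete panels use the Kronecker
    factorization; incomplete panels the dense observed-entry covariance.
    """
    beta_r = np.asarray(beta_r, dtype=float)
    if not np.all(np.isfinite(beta_r)):
        raise ValueError("beta_r must be finite")
    engine = _make_engine(panel)
    if beta_r.shape != (engine.p,):
        raise ValueError(f"beta_r must have shape ({engine.p},)")
    dec, logdetR = engine.decompose(params.rho_s, params.rho_t)
    z = engine.whiten_resid(dec, beta_r)
    n = engine.n
    return float(-0.5 * (n * np.log(2.0 * np.pi * params.sigma2)
                         + logdetR + z @ z / params.sigma2))


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class OzonePosterior:
    """Retained MCMC draws for the space-time ozone model."""
    beta: np.ndarray                 # (n_draws, p)
    sigma2: np.ndarray               # (n_draws,)
    rho_s: np.ndarray
    rho_t: np.ndarray
    coef_names: list
    accept_rate: float
    n_iter: int
    burn_in: int
    panel: LinkedPanel
    priors: GPPriors = field(default_factory=GPPriors)

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)

    def params_at(self, i: int) -> STCovarianceParams:
        return STCovarianceParams(float(self.sigma2[i]),
                                  float(self.rho_s[i]), float(self.rho_t[i]))

    def summary(self) -> pd.DataFrame:
        names = list(self.coef_names) + ["sigma2", "sigma", "rho_s", "rho_t"]
        cols = ([self.beta[:, k] for k in range(self.beta.shape[1])]
                + [self.sigma2, np.sqrt(self.sigma2), self.rho_s, self.rho_t])
        rows = []
        for name, v in zip(names, cols):
            rows.append((name, v.mean(), v.std(ddof=1),
                         np.percentile(v, 2.5), np.percentile(v, 97.5)))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "q2.5", "q97.5"])

    def to_frame(self) -> pd.DataFrame:
        """Long (iter, parameter, value) table of all retained draws."""
        names = list(self.coef_names) + ["sigma2", "rho_s", "rho_t"]
        vals = np.column_stack([self.beta, self.sigma2, self.rho_s,
                                self.rho_t])
        it = np.repeat(np.arange(self.n_draws), len(names))
        par = np.tile(names, self.n_draws)
        return pd.DataFrame({"iter": it, "parameter": par,
                             "value": vals.ravel()})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, panel: LinkedPanel,
                   priors: GPPriors | None = None) -> "OzonePosterior":
        """Rebuild a posterior from the long draw table and its panel."""
        wide = frame.pivot(index="iter", columns="parameter", values="value")
        coef_names = panel.coef_names()
        missing = [c for c in coef_names + ["sigma2", "rho_s", "rho_t"]
                   if c not in wide.columns]
        if missing:
            raise ValueError(f"draw table is missing parameters {missing}")
        n = len(wide)
        return cls(wide[coef_names].to_numpy(), wide["sigma2"].to_numpy(),
                   wide["rho_s"].to_numpy(), wide["rho_t"].to_numpy(),
                   coef_names, float("nan"), n, 0, panel,
                   priors or GPPriors())


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at the bounds."""
    width = hi - lo
    if width <= 0:
        raise ValueError("degenerate reflection interval")
    z = (x - lo) % (2.0 * width)
    return lo + (z if z <= width else 2.0 * width - z)


# lower floor for rho_t on the log scale; Uniform(0,5] prior mass below is
# negligible and exp(-d/rho) underflows anyway
_RHO_T_FLOOR = 1e-3


def fit_mcmc(panel: LinkedPanel, priors: GPPriors | None = None,
             n_iter: int = 4000, burn_in: int = 1000, seed: int = 0,
             sample_prior_only: bool = False) -> OzonePosterior:
    """Fit the space-time ozone model by MCMC.

    Gibbs updates for beta (conjugate normal) and sigma2 (conjugate
    inverse-gamma); joint random-walk Metropolis on (log rho_s, log rho_t)
    with reflection at the uniform-prior bounds and a prior-density
    Jacobian for the log-scale proposal.  Step sizes adapt during burn-in
    toward a 20-45% acceptance rate, then freeze.  ``n_iter`` counts total
    iterations; ``n_iter - burn_in`` draws are retained.

    ``sample_prior_only`` drops the likelihood terms so the chain targets
    the priors (prior predictive checking / sampler validation).
    """
    if priors is None:
        priors = GPPriors()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if panel.n_stations < 2 or panel.n_days < 2:
        raise ValueError("panel needs at least 2 stations and 2 days")
    engine = _make_engine(panel)
    obs_per_state = {}
    for st, row_ok in zip(panel.states, np.isfinite(panel.Y)):
        obs_per_state[st] = obs_per_state.get(st, 0) + int(row_ok.sum())
    for st, cnt in obs_per_state.items():
        if cnt < N_COEF:
            raise ValueError(f"state {st!r} has only {cnt} station-days; "
                             f"needs at least {N_COEF}")

    rng = np.random.default_rng(seed)
    p, n = engine.p, engine.n
    lo_s, hi_s = np.log(priors.rho_s_range[0]), np.log(priors.rho_s_range[1])
    lo_t = np.log(max(priors.rho_t_range[0], _RHO_T_FLOOR))
    hi_t = np.log(priors.rho_t_range[1])

    # initial values: mid-prior ranges, OLS-flavoured beta
    rho_s = float(np.exp(0.5 * (lo_s + hi_s)))
    rho_t = float(np.exp(0.5 * (lo_t + hi_t)))
    dec, logdetR = engine.decompose(rho_s, rho_t)
    Wx = engine.whiten_design(dec)
    Wy = engine.whiten_response(dec)
    gram = Wx.T @ Wx
    beta = np.linalg.solve(gram + priors.beta_precision * np.eye(p), Wx.T @ Wy)
    z = Wy - Wx @ beta
    sigma2 = float(max(z @ z / n, 1e-6))

    step = 0.05
    n_keep = n_iter - burn_in
    out_beta = np.empty((n_keep, p))
    out_s2 = np.empty(n_keep)
    out_rs = np.empty(n_keep)
    out_rt = np.empty(n_keep)
    accepted_post = 0
    block_acc, block_n = 0, 0
    lik = 0.0 if sample_prior_only else 1.0

    for it in range(n_iter):
        # --- beta | sigma2, rho, y (conjugate normal)
        A = lik * gram / sigma2 + priors.beta_precision * np.eye(p)
        b = lik * (Wx.T @ Wy) / sigma2
        cA, low = cho_factor(A)
        mean = cho_solve((cA, low), b)
        beta = mean + _chol_draw(A, rng)
        # --- sigma2 | beta, rho, y (conjugate inverse-gamma)
        z = Wy - Wx @ beta
        shape = priors.sigma2_shape + lik * 0.5 * n
        rate = priors.sigma2_rate + lik * 0.5 * float(z @ z)
        # gamma draws underflow to 0 for tiny shapes (prior-only runs)
        sigma2 = float(1.0 / max(rng.gamma(shape, 1.0 / rate), 1e-300))
        # --- (rho_s, rho_t) | beta, sigma2, y (random-walk Metropolis)
        q_cur = float(z @ z)
        prop_s = _reflect(np.log(rho_s) + step * rng.standard_normal(),
                          lo_s, hi_s)
        prop_t = _reflect(np.log(rho_t) + step * rng.standard_normal(),
                          lo_t, hi_t)
        new_rs, new_rt = float(np.exp(prop_s)), float(np.exp(prop_t))
        dec_new, logdet_new = engine.decompose(new_rs, new_rt)
        z_new = engine.whiten_resid(dec_new, beta)
        q_new = float(z_new @ z_new)
        if not np.isfinite(q_new):
            raise FloatingPointError(
                f"non-finite log posterior at iteration {it}")
        log_ratio = (lik * (-0.5) * (logdet_new - logdetR
                                     + (q_new - q_cur) / sigma2)
                     + (prop_s - np.log(rho_s)) + (prop_t - np.log(rho_t)))
        if np.log(rng.uniform()) < log_ratio:
            rho_s, rho_t = new_rs, new_rt
            dec, logdetR = dec_new, logdet_new
            Wx = engine.whiten_design(dec)
            Wy = engine.whiten_response(dec)
            gram = Wx.T @ Wx
            block_acc += 1
            if it >= burn_in:
                accepted_post += 1
        block_n += 1
        # adapt step toward 20-45% acceptance during burn-in only
        if it < burn_in and block_n == 25:
            rate_blk = block_acc / block_n
            if rate_blk > 0.45:
                step *= 1.5
            elif rate_blk < 0.20:
                step /= 1.5
            block_acc, block_n = 0, 0
        elif it == burn_in - 1:
            block_acc, block_n = 0, 0
        if it >= burn_in:
            k = it - burn_in
            out_beta[k] = beta
            out_s2[k] = sigma2
            out_rs[k] = rho_s
            out_rt[k] = rho_t

    return OzonePosterior(out_beta, out_s2, out_rs, out_rt,
                          panel.coef_names(), accepted_post / n_keep,
                          n_iter, burn_in, panel, priors)


def _chol_draw(A: np.ndarray, rng) -> np.ndarray:
    """Draw from N(0, A^-1) via the Cholesky factor of A."""
    L = np.linalg.cholesky(A)
    return solve_triangular(L.T, rng.standard_normal(len(A)), lower=False)


# ---------------------------------------------------------------------------
# posterior prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictiveDraws:
    """Posterior-predictive ozone fields at new stations.

    draws has shape (n_draws, m_stations, n_days); mean/lower/upper are
    pointwise summaries (95% predictive interval).
    """
    draws: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    station_ids: np.ndarray
    dates: np.ndarray


def _new_design(new_W: np.ndarray, new_states, state_levels) -> np.ndarray:
    m_s, n_t, _ = new_W.shape
    p = N_COEF * len(state_levels)
    X = np.zeros((m_s, n_t, p))
    base = np.concatenate([np.ones((m_s, n_t, 1)), new_W], axis=2)
    for i, st in enumerate(new_states):
        if st not in state_levels:
            raise ValueError(f"state {st!r} not present in the fitted panel")
        k = state_levels.index(st)
        X[i, :, k * N_COEF:(k + 1) * N_COEF] = base[i]
    return X


def predict(posterior: OzonePosterior, new_W: np.ndarray, new_states,
            new_coords: np.ndarray, new_dates=None, n_draws: int = 100,
            seed: int = 0, condition: bool = True,
            station_ids=None, draw_indices=None) -> PredictiveDraws:
    """Posterior-predictive draws of ozone at new stations.

    new_W : (m_s, n_t, 3) weather covariates (temp_c, ghi_wm2, cloud_pct)
    new_states : state label per new station (selects the coefficient block)
    new_coords : (m_s, 2) planar km
    condition : if True (kriging mode), draws are conditioned on the fitted
        panel's observed field; requires a complete panel and ``new_dates``
        equal to the panel's day grid.  If False (projection mode), draws
        come from the unconditional GP around X*beta — used for future
        periods where no ozone is observed, with the reference-period
        residual covariance carried forward.

    Returns pointwise means and 95% predictive intervals alongside draws.
    """
    panel = posterior.panel
    new_W = np.asarray(new_W, dtype=float)
    new_coords = np.asarray(new_coords, dtype=float)
    if new_W.ndim != 3 or new_W.shape[2] != 3:
        raise ValueError("new_W must have shape (m_stations, n_days, 3)")
    if not np.all(np.isfinite(new_W)):
        raise ValueError("new covariates must be finite")
    m_s, n_t = new_W.shape[:2]
    if new_coords.shape != (m_s, 2):
        raise ValueError("new_coords shape mismatch with new_W")
    if n_draws > posterior.n_draws:
        raise ValueError("n_draws exceeds retained posterior draws")
    if new_dates is None:
        new_dates = panel.dates if condition else np.arange(n_t).astype(str)
    new_dates = np.asarray(new_dates)
    if len(new_dates) != n_t:
        raise ValueError("new_dates length mismatch with new_W")

    X_new = _new_design(new_W, new_states, panel.state_levels)
    rng = np.random.default_rng(seed)
    if draw_indices is not None:
        idx = np.asarray(draw_indices, dtype=int)
        if len(idx) != n_draws:
            raise ValueError("draw_indices length must equal n_draws")
    else:
        idx = rng.choice(posterior.n_draws, size=n_draws, replace=False)

    if condition:
        if not panel.is_complete:
            raise ValueError("conditional prediction requires a complete panel")
        if n_t != panel.n_days or not np.array_equal(new_dates, panel.dates):
            raise ValueError("conditional prediction requires the panel's "
                             "day grid; use condition=False for new periods")
        Dt = panel.lag_matrix()
        d_oo = panel.distance_matrix()
        diff = new_coords[:, None, :] - panel.coords[None, :, :]
        d_no = np.sqrt((diff ** 2).sum(-1))
        diff2 = new_coords[:, None, :] - new_coords[None, :, :]
        d_nn = np.sqrt((diff2 ** 2).sum(-1))
        X_obs = panel.design_tensor()
    else:
        diff2 = new_coords[:, None, :] - new_coords[None, :, :]
        d_nn = np.sqrt((diff2 ** 2).sum(-1))
        tt = np.arange(n_t, dtype=float)
        Dt_new = np.abs(tt[:, None] - tt[None, :])

    draws = np.empty((n_draws, m_s, n_t))
    for j, i in enumerate(idx):
        beta = posterior.beta[i]
        s2 = float(posterior.sigma2[i])
        rs = float(posterior.rho_s[i])
        rt = float(posterior.rho_t[i])
        mean_new = X_new @ beta
        if condition:
            R_oo = np.exp(-d_oo / rs)
            R_no = np.exp(-d_no / rs)
            R_nn = np.exp(-d_nn / rs)
            c, low = cho_factor(R_oo + 1e-10 * np.eye(len(R_oo)))
            A = cho_solve((c, low), R_no.T).T          # (m_s, n_s)
            resid = panel.Y - X_obs @ beta
            mean_new = mean_new + A @ resid
            schur = R_nn - A @ R_no.T
            L_s = np.linalg.cholesky(schur + 1e-10 * np.eye(m_s))
            lam_t, U_t = _corr_eig(Dt, rt)
            L_t = U_t * np.sqrt(lam_t)
        else:
            L_s = np.linalg.cholesky(np.exp(-d_nn / rs)
                                     + 1e-10 * np.eye(m_s))
            lam_t, U_t = _corr_eig(Dt_new, rt)
            L_t = U_t * np.sqrt(lam_t)
        Z = rng.standard_normal((m_s, n_t))
        draws[j] = mean_new + np.sqrt(s2) * (L_s @ Z @ L_t.T)

    mean = draws.mean(axis=0)
    lower = np.percentile(draws, 2.5, axis=0)
    upper = np.percentile(draws, 97.5, axis=0)
    if station_ids is None:
        station_ids = np.array([f"new{i:03d}" for i in range(m_s)])
    return PredictiveDraws(draws, mean, lower, upper,
                           np.asarray(station_ids), new_dates)


def validate_holdout(panel: LinkedPanel, n_holdout: int = 10, seed: int = 0,
                     n_iter: int = 4000, burn_in: int = 1000,
                     n_draws: int = 100) -> tuple[float, float]:
    """Hold-out validation of the space-time model.

    Removes ``n_holdout`` whole stations at random (keeping at least one
    station per state so all coefficient blocks stay estimable), refits,
    predicts the held-out station-days by conditional kriging, and returns
    the prediction RMSE (ppb) and the fraction of 95% predictive intervals
    containing the held-out values.
    """
    if n_holdout >= panel.n_stations:
        raise ValueError("n_holdout must be smaller than the station count")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        hold = np.zeros(panel.n_stations, dtype=bool)
        hold[rng.choice(panel.n_stations, size=n_holdout, replace=False)] = True
        kept_states = set(panel.states[~hold].tolist())
        if kept_states == set(panel.state_levels):
            break
    else:
        raise ValueError("could not find a hold-out set keeping every state")

    train = panel.subset_stations(~hold)
    test = panel.subset_stations(hold)
    post = fit_mcmc(train, n_iter=n_iter, burn_in=burn_in, seed=seed + 1)
    pred = predict(post, test.W, test.states, test.coords,
                   new_dates=test.dates, n_draws=n_draws, seed=seed + 2,
                   condition=True, station_ids=test.station_ids)
    obs = test.Y
    ok = np.isfinite(obs)
    rmse = float(np.sqrt(np.mean((pred.mean[ok] - obs[ok]) ** 2)))
    coverage = float(np.mean((obs[ok] >= pred.lower[ok])
                             & (obs[ok] <= pred.upper[ok])))
    return rmse, coverage
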