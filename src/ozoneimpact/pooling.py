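"""Two-level normal hierarchical pooling of community risk estimates.

The community estimates are modelled as

    beta_hat_c ~ N(beta_c, v_c),    beta_c ~ N(mu, tau2),

with v_c treated as known.  The overall risk mu and the between-community
heterogeneity tau2 are estimated under a flat prior on mu and a uniform
prior on tau >= 0.  Rather than rejection sampling, the marginal
posterior of tau is integrated deterministically on a fine linear grid
(trapezoid rule); mu | tau is normal with inverse-variance weights
w_c = 1/(v_c + tau^2), so all posterior moments, the per-community
shrunken estimates E[beta_c | data] and the shrinkage factors
B_c = v_c/(v_c + tau^2) are mixture averages over the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: grid resolution for the tau integration
N_GRID = 2001
#: grid upper end: tau^2 spans 0 to TAU2_SPAN_FACTOR * max(v_c)
TAU2_SPAN_FACTOR = 20.0


@dataclass
class PooledRisk:
    """Posterior summary of the hierarchical pooling."""
    mu_mean: float                   # log-rate change per ppb
    mu_var: float
    tau2_mean: float
    shrunken: np.ndarray             # E[beta_c | data] per community
    community_ids: list
    betas: np.ndarray
    variances: np.ndarray
    lag_spec: str
    n_communities: int

    @property
    def mu_sd(self) -> float:
        return float(np.sqrt(self.mu_var))

    @property
    def pct_per_10ppb(self) -> float:
        return 100.0 * (np.exp(10.0 * self.mu_mean) - 1.0)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        return (self.mu_mean - z * self.mu_sd, self.mu_mean + z * self.mu_sd)


def _marginal_log_post(tau2: float, beta: np.ndarray, v: np.ndarray
                       ) -> tuple[float, float, float]:
    """log p(tau2-slice | data) up to a constant, with mu_hat and var(mu|tau)."""
    tv = v + tau2
    w = 1.0 / tv
    sw = w.sum()
    mu_hat = float((w * beta).sum() / sw)
    quad = float((w * (beta - mu_hat) ** 2).sum())
    logp = -0.5 * (np.log(tv).sum() + np.log(sw) + quad)
    return logp, mu_hat, 1.0 / sw


def pool(estimates, n_grid: int = N_GRID, tau_max: float | None = None
         ) -> PooledRisk:
    """Pool community risk estimates into an overall relative risk.

    ``estimates`` is a list of objects exposing ``beta_hat``, ``var_hat``,
    ``community_id`` and ``lag_spec`` (RiskEstimate).  All estimates must
    share a lag configuration; variances must be positive.
    """
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 estimates")
    lag_specs = {e.lag_spec for e in estimates}
    if len(lag_specs) != 1:
        raise ValueError(f"mixed lag configurations: {sorted(lag_specs)}")
    est = sorted(estimates, key=lambda e: str(e.community_id))
    beta = np.array([e.beta_hat for e in est], dtype=float)
    v = np.array([e.var_hat for e in est], dtype=float)
    if np.any(v <= 0):
        raise ValueError("estimation variances must be strictly positive")
    if tau_max is None:
        tau_max = float(np.sqrt(TAU2_SPAN_FACTOR * v.max()))
    tau = np.linspace(0.0, tau_max, n_grid)
    tau2 = tau ** 2

    logp = np.empty(n_grid)
    mu_hat = np.empty(n_grid)
    mu_condvar = np.empty(n_grid)
    for i, t2 in enumerate(tau2):
        logp[i], mu_hat[i], mu_condvar[i] = _marginal_log_post(t2, beta, v)
    w = np.exp(logp - logp.max())
    # trapezoid weights on the uniform tau grid (uniform prior on tau)
    trap = np.ones(n_grid)
    trap[0] = trap[-1] = 0.5
    w = w * trap
    w /= w.sum()

    mu_mean = float((w * mu_hat).sum())
    mu_var = float((w * (mu_condvar + mu_hat ** 2)).sum() - mu_mean ** 2)
    tau2_mean = float((w * tau2).sum())
    # shrunken community effects: E over tau of B_c*mu_hat + (1-B_c)*beta_c
    B = v[None, :] / (v[None, :] + tau2[:, None])      # (n_grid, n_c)
    shrunk_cond = B * mu_hat[:, None] + (1.0 - B) * beta[None, :]
    shrunken = (w[:, None] * shrunk_cond).sum(axis=0)
    return PooledRisk(mu_mean, mu_var, tau2_mean, shrunken,
                      [e.community_id for e in est], beta, v,
                      est[0].lag_spec, len(est))


def pool_fixed(estimates) -> tuple[float, float]:
    """Fixed-effect (tau2 = 0) inverse-variance-weighted pooled mean.

    Closed form: mu = sum(beta/v) / sum(1/v), var = 1/sum(1/v).
    """
    beta = np.array([e.beta_hat for e in estimates], dtype=float)
    v = np.array([e.var_hat for e in estimates], dtype=float)
    if np.any(v <= 0):
        raise ValueError("estimation variances must be strictly positive")
    w = 1.0 / v
    return float((w * beta).sum() / w.sum()), float(1.0 / w.sum())


def heterogeneity_summary(pooled: PooledRisk) -> dict:
    """Heterogeneity diagnostics for a pooled fit.

    Reports tau2, its ratio to the median within-community variance, and
    the per-community shrinkage factors B_c = v_c/(v_c + tau2) (1 = full
    pooling toward mu, 0 = no pooling).
    """
    med_v = float(np.median(pooled.variances))
    B = pooled.variances / (pooled.variances + pooled.tau2_mean)
    return {
        "tau2_mean": pooled.tau2_mean,
        "between_to_within_ratio": pooled.tau2_mean / med_v,
        "shrinkage_factors": dict(zip(pooled.community_ids, B.tolist())),
    }


def pooled_to_frame(pooled_by_lag: dict) -> pd.DataFrame:
    """Summary CSV layout across lag configurations."""
    rows = []
    for lag, p in pooled_by_lag.items():
        lo, hi = p.ci()
        rows.append({
            "lag_spec": lag, "mu_per_ppb": p.mu_mean, "sd": p.mu_sd,
            "pct_per_10ppb": p.pct_per_10ppb,
            "ci_low_per_ppb": lo, "ci_high_per_ppb": hi,
            "tau2": p.tau2_mean,
        })
    return pd.DataFrame(rows)
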