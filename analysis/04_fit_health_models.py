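"""Fit the community quasi-Poisson mortality models for each lag
configuration (lags 0/1/2 and the unconstrained distributed lag).

Reads results/data/mortality.csv; writes per-community risk estimates.

Usage: python analysis/04_fit_health_models.py [--results DIR]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ozoneimpact import health  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    ap.add_argument("--lags", default="lag0,lag1,lag2,dl02")
    args = ap.parse_args()
    res = Path(args.results)
    mortality = health.read_series(res / "data" / "mortality.csv")

    frames = []
    for lag in args.lags.split(","):
        ests = health.fit_all_communities(mortality, lag)
        frames.append(health.estimates_to_frame(ests))
        for e in ests:
            print(f"{lag:>5} {e.community_id}: "
                  f"{e.pct_per_10ppb:+.3f}% per 10 ppb "
                  f"(se {100 * 10 * e.var_hat ** 0.5:.3f}), "
                  f"dispersion {e.dispersion:.2f}, n={e.n_days} days")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(res / "risk_estimates.csv", index=False)
    print(f"wrote {len(out)} community risk estimates")


if __name__ == "__main__":
    main()
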