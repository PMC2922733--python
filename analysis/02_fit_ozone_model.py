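"""Fit the Bayesian space-time ozone-weather model to the linked panel
and validate it on held-out monitors.

Reads results/data/linked_panel.csv; writes the posterior draw table,
a summary with 95% intervals, and hold-out RMSE/coverage.

Usage: python analysis/02_fit_ozone_model.py [--seed N] [--results DIR]
       [--iters 4000] [--burn 1000]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ozoneimpact.spacetime import (fit_mcmc, read_panel,  # noqa: E402
                                   validate_holdout)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", default="results")
    ap.add_argument("--iters", type=int, default=4000)
    ap.add_argument("--burn", type=int, default=1000)
    ap.add_argument("--holdout", type=int, default=3)
    args = ap.parse_args()
    res = Path(args.results)
    panel = read_panel(res / "data" / "linked_panel.csv")

    post = fit_mcmc(panel, n_iter=args.iters, burn_in=args.burn,
                    seed=args.seed + 11)
    summary = post.summary()
    summary.to_csv(res / "ozone_posterior_summary.csv", index=False)
    post.to_frame().to_csv(res / "ozone_posterior_draws.csv", index=False)

    rmse, coverage = validate_holdout(
        panel, n_holdout=args.holdout, seed=args.seed + 12,
        n_iter=max(args.iters // 2, 500), burn_in=max(args.burn // 2, 100))
    pd.DataFrame([{"n_holdout": args.holdout, "rmse_ppb": rmse,
                   "coverage_95pi": coverage}]).to_csv(
        res / "holdout_validation.csv", index=False)

    show = summary.set_index("parameter")
    print(f"MCMC: {post.n_draws} retained draws, "
          f"acceptance {post.accept_rate:.2f}")
    for par in ("sigma", "rho_s", "rho_t"):
        r = show.loc[par]
        print(f"  {par:>6}: {r['mean']:.3g} [{r['q2.5']:.3g}, "
              f"{r['q97.5']:.3g}]")
    print(f"hold-out ({args.holdout} monitors): RMSE {rmse:.2f} ppb, "
          f"95% PI coverage {coverage:.2f}")


if __name__ == "__main__":
    main()
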