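"""Pool the community risk estimates into overall relative risks under
the two-level normal hierarchical model.

Reads results/risk_estimates.csv; writes the pooled summary and
heterogeneity diagnostics.

Usage: python analysis/05_pool_risks.py [--results DIR]
"""

import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ozoneimpact import pooling  # noqa: E402
from ozoneimpact.health import RiskEstimate  # noqa: E402


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", default="results")
    args = ap.parse_args()
    res = Path(args.results)
    table = pd.read_csv(res / "risk_estimates.csv")

    pooled = {}
    het = {}
    for lag, grp in table.groupby("lag_spec"):
        ests = [RiskEstimate(r.community, lag, r.beta_per_ppb, r.var,
                             r.dispersion, int(r.n))
                for r in grp.itertuples(index=False)]
        p = pooling.pool(ests)
        pooled[lag] = p
        het[lag] = pooling.heterogeneity_summary(p)
        print(f"{lag:>5}: {p.pct_per_10ppb:+.3f}% per 10 ppb "
              f"(mu {p.mu_mean:.2e} +- {p.mu_sd:.2e}, tau2 {p.tau2_mean:.2e})")
    pooling.pooled_to_frame(pooled).to_csv(res / "pooled_risk.csv",
                                           index=False)
    with open(res / "heterogeneity.json", "w") as fh:
        json.dump(het, fh, indent=2)
    print(f"wrote pooled risks for {len(pooled)} lag configurations")


if __name__ == "__main__":
    main()
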