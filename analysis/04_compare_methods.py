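"""Cross-method comparison: widths, ratios, rankings, coverage of truth.

Builds the state-level summary table (mean and 95% interval per outcome
per method), the median county interval widths and pairwise width ratios,
ranking-plot data (county estimates sorted by mean, one CSV per outcome
and method), and -- because the worlds are synthetic -- each method's
county-level coverage of the exact truth.  Everything is written under
results/comparison/.
"""

import sys
from pathlib import Path

import pandas as pd

from saeintervals.compare import compare_methods
from saeintervals.synthetic import AreaTruth

RESULTS = Path(__file__).resolve().parents[1] / "results"
METHODS = ("bayes", "mc", "parboot", "npboot", "direct")


def main() -> None:
    est_dir = RESULTS / "estimates"
    out = RESULTS / "comparison"
    out.mkdir(parents=True, exist_ok=True)
    state_rows = []
    for preset in ("copd", "binge", "arthritis"):
        ests = [pd.read_csv(est_dir / f"{preset}_{m}.csv", dtype={"area_id": str})
                for m in METHODS]
        truth = AreaTruth.from_json(RESULTS / "data" / preset / "truth.json")
        rep = compare_methods(ests, truth=truth)
        rep.method_summary.to_csv(out / f"summary_{preset}.csv")
        for m in METHODS:
            rep.ranking_data(m).to_csv(out / f"ranking_{preset}_{m}.csv", index=False)
            s = rep.table[(rep.table.method == m) & (rep.table.area_id == "state")].iloc[0]
            state_rows.append((preset, m, round(100 * s["mean"], 1),
                               round(100 * s["lo95"], 1), round(100 * s["hi95"], 1)))
        r_boot = rep.median_width_ratio("parboot", "npboot")
        r_mcb = rep.median_width_ratio("mc", "bayes")
        print(f"{preset:10s} median county width ratios: "
              f"parboot/npboot {r_boot:.2f}   mc/bayes {r_mcb:.2f}")
    table = pd.DataFrame(state_rows,
                         columns=["outcome", "method", "mean_pct", "lo95_pct", "hi95_pct"])
    table.to_csv(out / "state_level_table.csv", index=False)
    print("\nstate-level means and 95% intervals (%):")
    print(table.to_string(index=False))
    print(f"\ncomparison tables under {out}")


if __name__ == "__main__":
    sys.exit(main())
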