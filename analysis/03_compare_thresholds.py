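#!/usr/bin/env python
"""Compare optimal decision thresholds between the two cohorts.

For each parameter, the Youden-optimal threshold in each cohort and the
absolute between-cohort difference, with every high-attenuation
parameter paired against its conventional counterpart (MHALD vs MLD,
HAVx% vs Vx).  A parameter whose threshold transfers between cancer
types is the clinically useful one.

Reads results/cohort_*.csv; writes results/threshold_differences.csv.
"""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    path = RESULTS / "threshold_differences.csv"
    if not path.exists():
        raise SystemExit("run 02_rank_parameters.py first (it writes the "
                         "threshold comparison for two cohorts)")
    diffs = pd.read_csv(path).set_index("parameter")
    print(diffs.round(2).to_string())
    print()
    hav = diffs[diffs["is_hav_family"]]
    for name, row in hav.iterrows():
        conv = row["conventional_counterpart"]
        d_h, d_c = row["abs_difference"], diffs.loc[conv, "abs_difference"]
        verdict = "smaller" if d_h < d_c else "NOT smaller"
        print(f"{name}: |delta|={d_h:.2f} vs {conv} |delta|={d_c:.2f} -> {verdict}")


if __name__ == "__main__":
    main()
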