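#!/usr/bin/env python
"""Rank the DVH parameters by AUC for symptomatic RP in each cohort.

For every parameter: univariate logistic regression (odds ratio, Wald p)
and the ROC AUC; parameters sorted by AUC with the top three flagged —
the per-cohort "which parameter predicts pneumonitis best" table.

Reads the cohort tables from 01; writes results/auc_ranking_<label>.csv.
"""

from pathlib import Path

from havdvh.reporting_cli import DEFAULT_PARAMS, RunConfig, run_full_analysis

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tables = {p.stem.removeprefix("cohort_"): p
              for p in sorted(RESULTS.glob("cohort_*.csv"))}
    if not tables:
        raise SystemExit("no cohort tables found - run 01_simulate_cohorts.py first")
    report = run_full_analysis(RunConfig(tables=tables, output_dir=RESULTS))
    for label, data in report["cohorts"].items():
        top = [r["parameter"] for r in data["parameters"] if r["top3"]]
        print(f"{label}: top-3 by AUC = {', '.join(top)}")
        best = data["parameters"][0]
        print(f"  best: {best['parameter']} AUC={best['auc']:.3f} "
              f"threshold={best['optimal_threshold']:.2f} "
              f"(sens {best['sensitivity']:.2f}, spec {best['specificity']:.2f}), "
              f"OR/unit={best['odds_ratio_per_unit']:.2f}, p={best['wald_p']:.2g}")


if __name__ == "__main__":
    main()
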