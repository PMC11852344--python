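#!/usr/bin/env python
"""Aggregate per-subject measurements into the group-level cohort table.

Reads results/subject_results.csv (from 02_run_pipeline.py), builds the
mean ± SD / 95 % CI table per group and metric with percent differences of
each group against the isolated-myectomy reference, and writes
results/report/cohort_table.{csv,md}.
"""

import argparse
from pathlib import Path

import pandas as pd

from flow4d import AnalysisConfig, SubjectResult, build_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path,
                    default=Path("results/subject_results.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    df = pd.read_csv(args.results)
    results = [SubjectResult(**{k: (None if pd.isna(v) else v)
                                for k, v in row.items()})
               for row in df.to_dict("records")]
    table = build_report(results, AnalysisConfig(), out_dir=args.out)
    print(table.to_string(index=False))

    amvle = table[(table.group == "myectomy_amvle")
                  & table.metric.isin(["wss_aorta", "peak_velocity_lvot",
                                       "ke_lvot", "ke_aorta"])]
    print("\nmyectomy + AMVLE vs isolated myectomy (measured):")
    for _, r in amvle.iterrows():
        print(f"  {r.metric:20s} {r.pct_vs_reference:+.1f} %")


if __name__ == "__main__":
    main()
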