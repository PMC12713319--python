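#!/usr/bin/env python
"""Behavioral tabulations: report categories, covert detection, SDT, kappa.

Scores the simulated cohort's trial logs (report categories per M-trial,
covert-detection share, per-subject retrospective d') and, as a worked
example, reproduces the published report percentages from their printed
counts.  Tables go to results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from cbpupil.behavior import (covert_detection_share, per_subject_dprime,  # noqa: E402
                              percent, report_summary, tabulate_reports,
                              union_count)
from cbpupil.config import ExperimentConfig  # noqa: E402
from cbpupil.io import read_trial_log  # noqa: E402


def main() -> None:
    cohort = ROOT / "scratch" / "cohort_exp1"
    if not cohort.exists():
        sys.exit("no simulated cohort found; run analysis/01_simulate.py first")
    cfg = ExperimentConfig.from_yaml(cohort / "config.yaml")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    pooled = pd.concat(
        [read_trial_log(d / "trials.tsv", cfg).assign(subject=d.name)
         for d in sorted(cohort.iterdir()) if d.is_dir()], ignore_index=True)

    tabs = tabulate_reports(pooled)
    tabs["overall"].to_csv(results / "report_categories.tsv", sep="\t")
    n_m = int(tabs["overall"]["n"].sum())
    print(f"simulated cohort, {n_m} M-trials:")
    for cat, row in tabs["overall"].iterrows():
        print(f"  {cat:9s} {int(row['n']):4d}  ({row['pct']}%)")
    rr, unrep = covert_detection_share(pooled)
    print(f"covert-detection share: {rr}/{unrep} "
          f"({percent(rr, unrep, 1)}% of unreported M-trials)")
    dp = per_subject_dprime(pooled)
    dp.to_csv(results / "sdt_per_subject.tsv", sep="\t", index=False)
    print(f"retrospective discrimination: mean d' = {dp['d_prime'].mean():.3f} "
          f"(hit {dp['hit_rate'].mean():.3f}, FA {dp['fa_rate'].mean():.3f})")

    # worked example from the published aggregate counts
    exp1 = report_summary(185, 277, 160, 328)
    exp2 = dict(concurrent_pct=percent(110, 184, 2),
                retrospective_pct=percent(80, 184, 2),
                joint_pct=percent(union_count(110, 80, 58), 184, 1))
    worked = pd.DataFrame([{"experiment": "colored photographs", **exp1},
                           {"experiment": "monochrome faces", **exp2}])
    worked.to_csv(results / "published_tabulations.tsv", sep="\t", index=False)
    print("\npublished-count worked example:")
    print(f"  colored photographs: joint {exp1['joint_pct']}% "
          f"(union {exp1['joint_n']}/328), concurrent {exp1['concurrent_pct']}%, "
          f"retrospective {exp1['retrospective_pct']}%")
    print(f"  monochrome faces:    joint {exp2['joint_pct']}%, "
          f"concurrent {exp2['concurrent_pct']}%, "
          f"retrospective {exp2['retrospective_pct']}%")


if __name__ == "__main__":
    main()
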