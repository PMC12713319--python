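#!/usr/bin/env python
"""Leave-one-subject-out threshold classification of trial condition.

Classifies M- vs NM-trials, and concurrent report within M-trials, from
trial-level 2-4 s window pupil means using the midpoint-of-class-means
threshold learned from all other subjects; significance by exact
binomial test against the majority-class proportion.
"""

import importlib.util
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from cbpupil.classify import loso_classify  # noqa: E402
from cbpupil.inference import trial_window_values  # noqa: E402

spec = importlib.util.spec_from_file_location(
    "pupil_stats", Path(__file__).with_name("04_pupil_stats.py"))
pupil_stats = importlib.util.module_from_spec(spec)
spec.loader.exec_module(pupil_stats)


def main() -> None:
    epoch_sets, trials = pupil_stats.load_epochs()
    tv = trial_window_values(epoch_sets, trials)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cond = tv[tv["condition"].isin(("M", "NM"))]
    res = loso_classify(cond["value"], cond["condition"], cond["subject"],
                        positive="M", reference="NM")
    print(f"M vs NM: {res.n_correct}/{res.n_total} correct "
          f"({100 * res.accuracy:.1f}%), majority {100 * res.majority_proportion:.1f}%, "
          f"binomial p = {res.p_value:.2g}")
    res.predictions.to_csv(results / "classifier_condition.tsv", sep="\t",
                           index=False)

    m = tv[(tv["condition"] == "M") & (tv["report_category"] != "EXCLUDED")].copy()
    m["label"] = (m["report_category"] == "CR").map({True: "CR", False: "NCR"})
    res2 = loso_classify(m["value"], m["label"], m["subject"],
                         positive="CR", reference="NCR")
    print(f"CR vs NCR within M: {res2.n_correct}/{res2.n_total} correct "
          f"({100 * res2.accuracy:.1f}%), majority "
          f"{100 * res2.majority_proportion:.1f}%, binomial p = {res2.p_value:.2g}")
    res2.predictions.to_csv(results / "classifier_report.tsv", sep="\t",
                            index=False)


if __name__ == "__main__":
    main()
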