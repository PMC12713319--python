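#!/usr/bin/env python
"""Simulate a synthetic choice-blindness cohort and write it to disk.

Generates 16 subjects under the colored-photograph profile (30 trials,
8 M-trials at the fixed positions, 1000 Hz pupil traces with blinks,
saccades, drift and noise), writes per-subject samples/events/trials
TSVs under scratch/cohort_exp1/ plus the generator's ground truth, and
prints a behavioral summary.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from cbpupil.config import exp1_config  # noqa: E402
from cbpupil.io import write_subject_dir  # noqa: E402
from cbpupil.synth import generate_cohort  # noqa: E402

N_SUBJECTS = 16
SEED = 7

def main() -> None:
    cfg = exp1_config()
    out = ROOT / "scratch" / "cohort_exp1"
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    subjects, truth = generate_cohort(cfg, n_subjects=N_SUBJECTS, seed=SEED)
    for sd in subjects:
        write_subject_dir(sd.subject, sd.recording, sd.events, sd.trials, out)
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    m = truth[truth["condition"] == "M"]
    print(f"wrote {N_SUBJECTS} subjects to {out}")
    print(f"ground truth over {len(m)} M-trials:")
    print(f"  detected:              {100 * m['detected'].mean():.1f}%")
    print(f"  concurrently reported: {100 * m['reported_concurrent'].mean():.1f}%")
    print(f"  retrospectively rep.:  {100 * m['reported_retro'].mean():.1f}%")
    joint = (m["reported_concurrent"] | m["reported_retro"]).mean()
    print(f"  reported either way:   {100 * joint:.1f}%")


if __name__ == "__main__":
    main()
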