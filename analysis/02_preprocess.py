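#!/usr/bin/env python
"""Preprocess the simulated cohort and write epochs + a QC report.

Runs the full chain (blink interpolation, 0.02-4 Hz band-pass,
session-level z-scoring, 100 Hz decimation, canonical-IRF nuisance
regression, -1..5 s epoching, trial/subject QC) on every subject written
by 01_simulate.py, stores the epoch matrices under scratch/ and the QC
verdicts under results/qc_report.tsv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from cbpupil.config import ExperimentConfig  # noqa: E402
from cbpupil.io import read_subject_dir  # noqa: E402
from cbpupil.preprocess import preprocess_session  # noqa: E402


def main() -> None:
    cohort = ROOT / "scratch" / "cohort_exp1"
    if not cohort.exists():
        sys.exit("no simulated cohort found; run analysis/01_simulate.py first")
    cfg = ExperimentConfig.from_yaml(cohort / "config.yaml")
    out = ROOT / "scratch" / "epochs_exp1"
    out.mkdir(parents=True, exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)

    rows = []
    for subj_dir in sorted(d for d in cohort.iterdir() if d.is_dir()):
        rec, events, trials = read_subject_dir(subj_dir, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep, verdict = preprocess_session(rec, events, trials, cfg,
                                             subject=subj_dir.name)
        rows.append(dict(subject=subj_dir.name, n_trials=verdict.n_trials,
                         n_excluded=verdict.n_excluded,
                         subject_excluded=verdict.subject_excluded,
                         session_scale=ep.session_scale))
        if not verdict.subject_excluded:
            np.savez(out / f"{subj_dir.name}.npz", data=ep.data,
                     times=ep.times, trial_keys=ep.trial_keys,
                     invalid_fraction=ep.invalid_fraction,
                     included=ep.included, session_scale=ep.session_scale)
    qc = pd.DataFrame(rows)
    qc.to_csv(ROOT / "results" / "qc_report.tsv", sep="\t", index=False)
    kept = (~qc["subject_excluded"]).sum()
    print(f"preprocessed {len(qc)} subjects, kept {kept}")
    print(f"median excluded trials per subject: {qc['n_excluded'].median():.1f}")
    print(f"QC report -> results/qc_report.tsv; epochs -> {out}")


if __name__ == "__main__":
    main()
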