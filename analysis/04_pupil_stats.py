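#!/usr/bin/env python
"""Pupil statistics: pointwise FDR tests, window analysis, mixed models.

Loads the preprocessed epochs, builds subject-level condition means,
runs the one-sided pointwise paired t-tests (M > NM, M > baseline) with
Benjamini-Hochberg correction over 0-5 s, the 2-4 s window battery, and
the trial-level linear mixed models (trial type; reporting category;
trial order + confidence) with ICC.  Tables go to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from cbpupil.config import ExperimentConfig  # noqa: E402
from cbpupil.datatypes import EpochSet  # noqa: E402
from cbpupil.inference import (fit_pupil_lmm, pointwise_paired_tests,  # noqa: E402
                               subject_condition_means, trial_window_values,
                               window_analysis)
from cbpupil.io import read_trial_log  # noqa: E402


def load_epochs():
    cohort = ROOT / "scratch" / "cohort_exp1"
    epodir = ROOT / "scratch" / "epochs_exp1"
    if not epodir.exists():
        sys.exit("no epochs found; run analysis/02_preprocess.py first")
    cfg = ExperimentConfig.from_yaml(cohort / "config.yaml")
    epoch_sets, trials = {}, {}
    for f in sorted(epodir.glob("*.npz")):
        z = np.load(f)
        subj = f.stem
        epoch_sets[subj] = EpochSet(
            data=z["data"], times=z["times"], trial_keys=z["trial_keys"],
            invalid_fraction=z["invalid_fraction"], included=z["included"],
            rate=cfg.target_rate_hz, session_scale=float(z["session_scale"]),
            subject=subj)
        trials[subj] = read_trial_log(cohort / subj / "trials.tsv", cfg)
    return epoch_sets, trials


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    epoch_sets, trials = load_epochs()
    print(f"{len(epoch_sets)} subjects with usable epochs")

    means = subject_condition_means(epoch_sets, trials)
    series = []
    for a, b in (("M", "NM"), ("M", "BASE")):
        res = pointwise_paired_tests(means[a], means[b], contrast=f"{a}>{b}")
        n_sig = int(res.fdr_mask.sum())
        first = res.time_s[res.fdr_mask][0] if n_sig else np.nan
        print(f"{a} > {b}: {n_sig}/501 time points survive FDR"
              + (f" (first at {first:.2f} s)" if n_sig else ""))
        series.append(pd.DataFrame(dict(contrast=res.contrast,
                                        time_s=res.time_s, t=res.t_stat,
                                        p=res.p_uncorrected,
                                        fdr_sig=res.fdr_mask)))
    pd.concat(series).to_csv(results / "pointwise_tests.tsv", sep="\t",
                             index=False)

    wm, battery = window_analysis(epoch_sets, trials)
    wm.to_csv(results / "window_stats.tsv", sep="\t", index=False)
    battery.to_csv(results / "window_tests.tsv", sep="\t", index=False)
    headline = battery[battery["contrast"].isin(("M vs BASE", "M vs NM"))]
    for _, r in headline.iterrows():
        print(f"window 2-4 s, {r['contrast']}: t = {r['t']:.2f}, "
              f"p = {r['p']:.4g} (n = {r['n']})")

    tv = trial_window_values(epoch_sets, trials)
    tv.to_csv(results / "trial_window_values.tsv", sep="\t", index=False)
    mn = tv[tv["condition"].isin(("M", "NM"))].copy()
    mn["is_m"] = (mn["condition"] == "M").astype(int)
    m1 = fit_pupil_lmm(mn, "value ~ is_m")
    print(f"LMM trial type: beta_M = {m1.params.loc['is_m', 'beta']:.3f}, "
          f"ICC = {m1.icc:.3f}")
    m3 = fit_pupil_lmm(tv[tv["condition"] == "M"],
                       "value ~ m_order + confidence")
    print(f"LMM M-trials: beta_order = {m3.params.loc['m_order', 'beta']:.4f}, "
          f"beta_conf = {m3.params.loc['confidence', 'beta']:.4f}, "
          f"ICC = {m3.icc:.3f}")


if __name__ == "__main__":
    main()
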