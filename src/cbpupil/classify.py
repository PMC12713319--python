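"""Leave-one-subject-out midpoint-threshold pupil classifier.

For each held-out subject, the threshold is the midpoint between the
mean window pupil response of the two classes computed from all OTHER
subjects' trials (pooled over trials by default; a mean-of-subject-means
variant is available).  A trial is predicted as the positive class iff
its value strictly exceeds the threshold (ties go to the reference
class, conservative toward chance).  Significance is an exact one-sided
binomial test of pooled accuracy against the majority-class proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom


@dataclass
class ClassifierResult:
    predictions: pd.DataFrame     # subject, value, label, predicted, correct
    n_correct: int
    n_total: int
    accuracy: float
    majority_proportion: float
    p_value: float
    n_skipped_folds: int


def binomial_vs_majority(n_correct: int, n_total: int, p0: float) -> float:
    """Exact one-sided tail P(X >= n_correct | n_total, p0)."""
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must lie in 0..n_total")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    return float(binom.sf(n_correct - 1, n_total, p0))


def loso_classify(values, labels, subjects, *, positive: str, reference: str,
                  training: str = "pooled") -> ClassifierResult:
    """Leave-one-subject-out midpoint-threshold classification.

    ``values`` are trial-level window pupil means; ``labels`` the true
    classes (e.g. M/NM or CR/NCR); ``subjects`` the fold keys.  Folds
    whose training set lacks a class are skipped with a warning.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "label": np.asarray(labels, dtype=object),
                       "subject": np.asarray(subjects, dtype=object)})
    classes = set(df["label"])
    if not classes <= {positive, reference}:
        raise ValueError(f"labels {sorted(classes)} not in "
                         f"{{{positive}, {reference}}}")
    uniq = df["subject"].unique()
    if len(uniq) < 2:
        raise ValueError("need >= 2 subjects for leave-one-subject-out")

    preds = []
    n_skipped = 0
    for subj in uniq:
        train = df[df["subject"] != subj]
        test = df[df["subject"] == subj]
        if training == "pooled":
            mean_pos = train.loc[train["label"] == positive, "value"].mean()
            mean_ref = train.loc[train["label"] == reference, "value"].mean()
        elif training == "subject_means":
            by = train.groupby(["subject", "label"])["value"].mean().unstack()
            mean_pos = by[positive].mean() if positive in by else np.nan
            mean_ref = by[reference].mean() if reference in by else np.nan
        else:
            raise ValueError(f"unknown training rule {training!r}")
        if not (np.isfinite(mean_pos) and np.isfinite(mean_ref)):
            warnings.warn(f"fold {subj!r}: training set lacks a class; skipped")
            n_skipped += 1
            continue
        thr = 0.5 * (mean_pos + mean_ref)
        out = test.copy()
        out["predicted"] = np.where(out["value"] > thr, positive, reference)
        out["threshold"] = thr
        preds.append(out)

    if not preds:
        raise ValueError("no classifiable folds")
    pred = pd.concat(preds, ignore_index=True)
    pred["correct"] = pred["predicted"] == pred["label"]
    n_total = len(pred)
    n_correct = int(pred["correct"].sum())
    counts = df["label"].value_counts()
    p0 = float(counts.max() / counts.sum())
    return ClassifierResult(
        predictions=pred, n_correct=n_correct, n_total=n_total,
        accuracy=n_correct / n_total, majority_proportion=p0,
        p_value=binomial_vs_majority(n_correct, n_total, p0),
        n_skipped_folds=n_skipped)
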