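"""Report categories, behavioral tabulations, signal detection, interrater kappa.

Category schema for M-trials, derived from the concurrent verbal-report
code and the retrospective memory-task flag:

* CR  — concurrent report (the subject flagged the mismatch during the
  trial); "possible detection" trials that WERE retrospectively reported
  are counted here as well, distinctly flagged.
* RR  — retrospective-only report (no concurrent report, but the pair was
  correctly identified in the post-experiment memory task).
* NR  — no report on either occasion.
* EXCLUDED — "possible detection" with no retrospective confirmation;
  dropped from all analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import norm

CATEGORIES = ("CR", "RR", "NR", "EXCLUDED")


def derive_category(concurrent_code: str, retrospective_flag: bool) -> str:
    """Map (concurrent code, retrospective flag) to a report category."""
    if concurrent_code == "report":
        return "CR"
    if concurrent_code == "possible":
        return "CR" if retrospective_flag else "EXCLUDED"
    if concurrent_code == "none":
        return "RR" if retrospective_flag else "NR"
    raise ValueError(f"unknown concurrent code {concurrent_code!r}")


def add_report_categories(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a ``report_category`` column (M-trials only; others empty)."""
    out = trials.copy()
    cats = []
    for _, row in out.iterrows():
        if row["condition"] == "M":
            cats.append(derive_category(row["concurrent_code"],
                                        bool(row["retrospective_flag"])))
        else:
            cats.append("")
    out["report_category"] = cats
    return out


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """100*count/denominator, rounded half-up to ``decimals`` places.

    Returns NaN for a zero denominator (undefined, reported as missing).
    """
    if denominator == 0:
        return float("nan")
    q = Decimal(10) ** -decimals
    val = Decimal(100) * Decimal(count) / Decimal(denominator)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


def union_count(n_concurrent: int, n_retrospective: int, n_both: int) -> int:
    """Trials reported concurrently OR retrospectively (inclusion-exclusion)."""
    if n_both > min(n_concurrent, n_retrospective):
        raise ValueError("overlap exceeds a marginal count")
    return n_concurrent + n_retrospective - n_both


def report_summary(n_concurrent: int, n_retrospective: int, n_both: int,
                   n_total: int) -> dict[str, float]:
    """Headline reporting percentages from aggregate counts.

    Keys: ``joint_pct`` (concurrent or retrospective), ``concurrent_pct``,
    ``retrospective_pct``, ``concurrent_also_retro_pct``; counts under
    ``*_n``.
    """
    n_union = union_count(n_concurrent, n_retrospective, n_both)
    return {
        "joint_n": n_union,
        "joint_pct": percent(n_union, n_total, 1),
        "concurrent_pct": percent(n_concurrent, n_total, 1),
        "retrospective_pct": percent(n_retrospective, n_total, 2),
        "concurrent_also_retro_pct": percent(n_both, n_concurrent, 1),
    }


def tabulate_reports(trials: pd.DataFrame,
                     subject_col: str = "subject") -> dict[str, pd.DataFrame]:
    """Category counts/percentages over the M-trials of one or more subjects.

    Returns tables keyed ``overall`` (per category), ``by_position``
    (per M-trial order) and ``by_subject``.  EXCLUDED trials are kept as
    their own row so that totals are conserved.
    """
    if "report_category" not in trials.columns:
        trials = add_report_categories(trials)
    m = trials[trials["condition"] == "M"].copy()
    if subject_col not in m.columns:
        m[subject_col] = "s001"
    m = m.sort_values([subject_col, "trial_idx"])
    m["m_order"] = m.groupby(subject_col).cumcount() + 1

    total = len(m)
    overall = (m["report_category"].value_counts()
               .reindex(CATEGORIES, fill_value=0).rename("n").to_frame())
    overall["pct"] = [percent(v, total, 1) for v in overall["n"]]

    by_pos = (m.pivot_table(index="m_order", columns="report_category",
                            values="trial_idx", aggfunc="count", fill_value=0))
    by_subj = (m.pivot_table(index=subject_col, columns="report_category",
                             values="trial_idx", aggfunc="count", fill_value=0))
    return {"overall": overall, "by_position": by_pos, "by_subject": by_subj}


def covert_detection_share(trials: pd.DataFrame) -> tuple[int, int]:
    """(retro-only reports, all non-concurrently-reported M-trials).

    The covert-detection estimate is the share of unreported M-trials that
    were nevertheless retrospectively identified (RR among RR+NR).
    """
    if "report_category" not in trials.columns:
        trials = add_report_categories(trials)
    m = trials[trials["condition"] == "M"]
    n_rr = int((m["report_category"] == "RR").sum())
    n_nr = int((m["report_category"] == "NR").sum())
    return n_rr, n_rr + n_nr


# ---------------------------------------------------------------------------
# signal detection

@dataclass
class SDTResult:
    hit_rate: float
    fa_rate: float
    d_prime: float
    correction_applied: str


def sdt_score(n_hits: int, n_misses: int, n_fa: int, n_cr: int,
              correction: str = "loglinear") -> SDTResult:
    """d' = Phi^-1(H) - Phi^-1(F) from raw counts.

    The log-linear correction adds 0.5 to every cell before computing
    rates whenever a raw rate would be 0 or 1; with ``correction="none"``
    such rates raise (infinite d').
    """
    for v in (n_hits, n_misses, n_fa, n_cr):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_signal, n_noise = n_hits + n_misses, n_fa + n_cr
    if n_signal == 0 or n_noise == 0:
        raise ValueError("signal and noise totals must be positive")
    H = n_hits / n_signal
    F = n_fa / n_noise
    applied = "none"
    if H in (0.0, 1.0) or F in (0.0, 1.0):
        if correction == "none":
            raise ValueError("extreme rate gives infinite d'; use loglinear")
        H = (n_hits + 0.5) / (n_signal + 1.0)
        F = (n_fa + 0.5) / (n_noise + 1.0)
        applied = "loglinear"
    return SDTResult(hit_rate=H, fa_rate=F,
                     d_prime=float(norm.ppf(H) - norm.ppf(F)),
                     correction_applied=applied)


def sdt_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' directly from (non-extreme) rates."""
    if not (0 < hit_rate < 1 and 0 < fa_rate < 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def per_subject_dprime(trials: pd.DataFrame, n_noise_pairs: int = 22,
                       subject_col: str = "subject") -> pd.DataFrame:
    """Retrospective-discrimination SDT per subject (log-linear corrected).

    Hits: M-trials retrospectively reported; false alarms: non-M pairs
    wrongly named in the memory task, out of ``n_noise_pairs`` presented.
    """
    rows = []
    for subj, grp in trials.groupby(subject_col):
        m = grp[grp["condition"] == "M"]
        hits = int(m["retrospective_flag"].sum())
        misses = len(m) - hits
        fa = int(grp.loc[grp["condition"] != "M",
                         "retro_false_positive_flag"].sum())
        res = sdt_score(hits, misses, fa, n_noise_pairs - fa)
        rows.append(dict(subject=subj, hit_rate=res.hit_rate,
                         fa_rate=res.fa_rate, d_prime=res.d_prime))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interrater agreement

@dataclass
class KappaResult:
    kappa: float
    percent_agreement: float
    undefined: bool = False


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa and raw percent agreement for two coders' labels."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    cats = np.union1d(a, b)
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if abs(1.0 - p_e) < 1e-12:
        return KappaResult(kappa=float("nan"), percent_agreement=100 * p_o,
                           undefined=True)
    return KappaResult(kappa=(p_o - p_e) / (1.0 - p_e),
                       percent_agreement=100 * p_o)
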