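"""Time-series and window statistics, FDR control, and mixed models.

Pointwise tests are paired t-tests across subjects on per-subject,
per-condition mean traces, computed over 0..5 s after test-image onset
(501 points at 100 Hz) and corrected with Benjamini-Hochberg within each
contrast.  One-sided tests are used for directional contrasts (M > NM,
M > baseline).  The window analysis averages 2..4 s after onset and
normalizes each subject's condition means by subtracting their
baseline-trial window mean.

The report model is a logistic mixed model with a subject random
intercept, fit by maximum likelihood with the random effect integrated
out by Gauss-Hermite quadrature (statsmodels has no ML estimator for
binomial mixed models; its Bayesian variational fit serves as an
independent cross-check in the test suite).  The pupil window model is a
linear mixed model via statsmodels MixedLM, with the intraclass
correlation ICC = sigma2_subject / (sigma2_subject + sigma2_residual).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .behavior import add_report_categories
from .datatypes import EpochSet

M_SUBCATEGORIES = ("CR", "NCR", "RR", "NR")


# ---------------------------------------------------------------------------
# FDR

def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    mask, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return mask


# ---------------------------------------------------------------------------
# subject-level condition means

def subject_condition_means(epoch_sets: dict[str, EpochSet],
                            trials_by_subject: dict[str, pd.DataFrame]
                            ) -> dict[str, pd.DataFrame]:
    """Per-subject mean epoch traces per condition.

    Conditions: M, NM, BASE, and within M the report categories CR,
    NCR (= RR + NR, i.e. not concurrently reported), RR, NR.  EXCLUDED
    M-trials are dropped.  Returns {condition: DataFrame(subject x time)}.
    """
    groups: dict[str, dict[str, np.ndarray]] = {}
    for subj, ep in epoch_sets.items():
        trials = add_report_categories(trials_by_subject[subj])
        trials = trials.set_index("trial_idx")
        cond = trials.loc[ep.trial_keys, "condition"].to_numpy()
        cat = trials.loc[ep.trial_keys, "report_category"].to_numpy()
        sel = {
            "M": (cond == "M") & (cat != "EXCLUDED"),
            "NM": cond == "NM",
            "BASE": cond == "BASE",
            "CR": cat == "CR",
            "NCR": np.isin(cat, ("RR", "NR")),
            "RR": cat == "RR",
            "NR": cat == "NR",
        }
        for name, m in sel.items():
            m = m & ep.included
            if m.any():
                groups.setdefault(name, {})[subj] = ep.data[m].mean(axis=0)
    times = next(iter(epoch_sets.values())).times
    return {name: pd.DataFrame.from_dict(d, orient="index", columns=times)
            for name, d in groups.items()}


# ---------------------------------------------------------------------------
# pointwise paired tests

@dataclass
class PointwiseTestSeries:
    contrast: str
    sided: str
    time_s: np.ndarray
    t_stat: np.ndarray
    p_uncorrected: np.ndarray
    fdr_mask: np.ndarray
    uncorrected_mask: np.ndarray
    n_subjects: int
    q: float


def _paired_t(diff: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized one-sample t over axis 0; returns (t, df)."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0,
                     np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t, n - 1


def pointwise_paired_tests(means_a: pd.DataFrame, means_b: pd.DataFrame,
                           contrast: str = "A>B", sided: str = "greater",
                           q: float = 0.05, alpha: float = 0.05,
                           t_range: tuple[float, float] = (0.0, 5.0)
                           ) -> PointwiseTestSeries:
    """Paired t-test per time point on subject-level mean traces.

    Rows are subjects (paired by index, order-independent), columns are
    times in seconds; the test family is restricted to ``t_range``.
    """
    common = means_a.index.intersection(means_b.index)
    if len(common) < 2:
        raise ValueError("need >= 2 subjects present in both conditions")
    times = np.asarray(means_a.columns, dtype=float)
    sel = (times >= t_range[0] - 1e-9) & (times <= t_range[1] + 1e-9)
    diff = (means_a.loc[common].to_numpy() - means_b.loc[common].to_numpy())[:, sel]
    t, df = _paired_t(diff)
    if sided == "greater":
        p = stats.t.sf(t, df)
    elif sided == "two-sided":
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return PointwiseTestSeries(
        contrast=contrast, sided=sided, time_s=times[sel], t_stat=t,
        p_uncorrected=p, fdr_mask=fdr_bh(p, q), uncorrected_mask=p <= alpha,
        n_subjects=len(common), q=q)


# ---------------------------------------------------------------------------
# window analysis

def window_means(epoch_sets: dict[str, EpochSet],
                 trials_by_subject: dict[str, pd.DataFrame],
                 window: tuple[float, float] = (2.0, 4.0),
                 baseline_normalize: bool = True) -> pd.DataFrame:
    """Subject x condition mean pupil over the analysis window.

    Values are condition means minus the subject's baseline-trial window
    mean (so BASE is 0 by construction) unless ``baseline_normalize`` is
    off.  Long format: subject, condition, value, n_trials.
    """
    rows = []
    for subj, ep in epoch_sets.items():
        trials = add_report_categories(trials_by_subject[subj]).set_index("trial_idx")
        tsel = (ep.times >= window[0] - 1e-9) & (ep.times <= window[1] + 1e-9)
        wvals = ep.data[:, tsel].mean(axis=1)
        cond = trials.loc[ep.trial_keys, "condition"].to_numpy()
        cat = trials.loc[ep.trial_keys, "report_category"].to_numpy()
        sel = {
            "M": (cond == "M") & (cat != "EXCLUDED"),
            "NM": cond == "NM",
            "BASE": cond == "BASE",
            "CR": cat == "CR",
            "NCR": np.isin(cat, ("RR", "NR")),
            "RR": cat == "RR",
            "NR": cat == "NR",
        }
        base_m = sel["BASE"] & ep.included
        base = wvals[base_m].mean() if base_m.any() else np.nan
        for name, m in sel.items():
            m = m & ep.included
            if not m.any():
                continue
            v = wvals[m].mean()
            if baseline_normalize:
                v = v - base
            rows.append(dict(subject=subj, condition=name, value=v,
                             n_trials=int(m.sum())))
    return pd.DataFrame(rows)


def trial_window_values(epoch_sets: dict[str, EpochSet],
                        trials_by_subject: dict[str, pd.DataFrame],
                        window: tuple[float, float] = (2.0, 4.0)) -> pd.DataFrame:
    """Trial-level window means (inputs to mixed models and the classifier)."""
    rows = []
    for subj, ep in epoch_sets.items():
        trials = add_report_categories(trials_by_subject[subj]).set_index("trial_idx")
        tsel = (ep.times >= window[0] - 1e-9) & (ep.times <= window[1] + 1e-9)
        wvals = ep.data[:, tsel].mean(axis=1)
        m_order = {idx: k + 1 for k, idx in enumerate(
            sorted(trials.index[trials["condition"] == "M"]))}
        for row_i, tid in enumerate(ep.trial_keys):
            if not ep.included[row_i]:
                continue
            rows.append(dict(
                subject=subj, trial_idx=int(tid),
                condition=trials.loc[tid, "condition"],
                report_category=trials.loc[tid, "report_category"],
                m_order=m_order.get(int(tid), 0),
                confidence=trials.loc[tid, "confidence"],
                value=wvals[row_i]))
    return pd.DataFrame(rows)


def window_analysis(epoch_sets: dict[str, EpochSet],
                    trials_by_subject: dict[str, pd.DataFrame],
                    window: tuple[float, float] = (2.0, 4.0)
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window stats + the paired-test battery.

    M-family conditions (M, CR, NCR, RR, NR) are tested against baseline
    trials (one-sided), against NM-trials (one-sided) and against each
    other (two-sided); NM is tested against baseline two-sided.  A
    comparison with fewer than 2 paired subjects is reported as
    not-estimable (NaN).
    """
    wm = window_means(epoch_sets, trials_by_subject, window)
    wide = wm.pivot(index="subject", columns="condition", values="value")

    def paired(a: str, b: str, sided: str) -> dict:
        if a not in wide or b not in wide:
            sub = pd.DataFrame()
        else:
            sub = wide[[a, b]].dropna()
        if len(sub) < 2:
            return dict(contrast=f"{a} vs {b}", sided=sided, n=len(sub),
                        t=np.nan, p=np.nan, estimable=False)
        d = sub[a] - sub[b]
        t, df = _paired_t(d.to_numpy()[:, None])
        t = float(t[0])
        p = stats.t.sf(t, df) if sided == "greater" else 2 * stats.t.sf(abs(t), df)
        return dict(contrast=f"{a} vs {b}", sided=sided, n=len(sub),
                    t=t, p=float(p), estimable=True)

    tests = []
    fam = ["M", "CR", "NCR", "RR", "NR"]
    for c in fam:
        tests.append(paired(c, "BASE", "greater"))
        tests.append(paired(c, "NM", "greater"))
    for i, a in enumerate(fam[1:], start=1):
        for b in fam[i + 1:]:
            tests.append(paired(a, b, "two-sided"))
    tests.append(paired("NM", "BASE", "two-sided"))
    return wm, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# logistic mixed model (subject random intercept) by ML / Gauss-Hermite

@dataclass
class GLMMResult:
    params: pd.DataFrame          # per fixed effect: beta, OR, CI, p
    sigma2_subject: float
    converged: bool
    separation_flag: bool
    loglik: float


def _glmm_nll(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
              groups: np.ndarray, nodes: np.ndarray, wts: np.ndarray,
              with_grad: bool = False):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    # (n_obs, n_nodes) linear predictor with scaled quadrature offsets
    u = np.sqrt(2.0) * sigma * nodes
    z = eta[:, None] + u[None, :]
    loglik_obs = np.where(y[:, None] == 1, -np.logaddexp(0, -z),
                          -np.logaddexp(0, z))
    # sum within subject, then integrate
    n_groups = groups.max() + 1
    per_group = np.zeros((n_groups, len(nodes)))
    np.add.at(per_group, groups, loglik_obs)
    m = per_group.max(axis=1, keepdims=True)
    w = wts / np.sqrt(np.pi)
    inner = w * np.exp(per_group - m)          # (G, K)
    denom = inner.sum(axis=1)
    nll = -float((np.log(denom) + m[:, 0]).sum())
    if not with_grad:
        return nll
    post = inner / denom[:, None]              # node posteriors per group
    resid = y[:, None] - 1.0 / (1.0 + np.exp(-z))   # (n_obs, K)
    q = post[groups] * resid
    grad_beta = -X.T @ q.sum(axis=1)
    grad_s = -np.sqrt(2.0) * sigma * float((q * nodes[None, :]).sum())
    return nll, np.concatenate([grad_beta, [grad_s]])


def fit_report_glmm(trials: pd.DataFrame, outcome: str = "concurrent",
                    fixed: tuple[str, ...] = ("m_order", "confidence",
                                              "dissimilar"),
                    n_quad: int = 25) -> GLMMResult:
    """Logistic mixed model of M-trial reporting with subject intercepts.

    ``trials`` needs columns ``subject``, the fixed-effect covariates and
    either an ``outcome`` column (0/1) or report codes from which the
    outcome is derived (``concurrent``: concurrent_code == 'report';
    ``retrospective``: retrospective_flag).  EXCLUDED trials are dropped.
    Wald CIs; odds ratios are exp(beta).
    """
    df = trials.copy()
    if "outcome" not in df.columns:
        df = add_report_categories(df)
        df = df[(df["condition"] == "M") & (df["report_category"] != "EXCLUDED")]
        if outcome == "concurrent":
            df["outcome"] = (df["concurrent_code"] == "report").astype(int)
        elif outcome == "retrospective":
            df["outcome"] = df["retrospective_flag"].astype(int)
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        if "m_order" in fixed and "m_order" not in df.columns:
            df = df.sort_values(["subject", "trial_idx"])
            df["m_order"] = df.groupby("subject").cumcount() + 1
        if "dissimilar" in fixed and "dissimilar" not in df.columns:
            df["dissimilar"] = (df["similarity"] == "dissimilar").astype(int)

    y = df["outcome"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(dtype=float) for c in fixed])
    names = ["intercept", *fixed]
    groups, _ = pd.factorize(df["subject"])

    separation = bool(y.min() == y.max())
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)

    x0 = np.zeros(X.shape[1] + 1)
    res = optimize.minimize(
        _glmm_nll, x0, args=(X, y, groups, nodes, wts, True), jac=True,
        method="BFGS", options=dict(maxiter=500, gtol=1e-6))
    theta = res.x
    if np.any(np.abs(theta[:-1]) > 15):
        separation = True

    def f(th):
        return _glmm_nll(th, X, y, groups, nodes, wts)
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h[i]
            ej = np.eye(k)[j] * h[j]
            H[i, j] = H[j, i] = (f(theta + ei + ej) - f(theta + ei - ej)
                                 - f(theta - ei + ej) + f(theta - ei - ej)
                                 ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_all = np.full(k, np.nan)

    beta = theta[:-1]
    se = se_all[:-1]
    zcrit = stats.norm.ppf(0.975)
    rows = []
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        zstat = beta / se
        for i, name in enumerate(names):
            rows.append(dict(
                effect=name, beta=beta[i], se=se[i],
                odds_ratio=float(np.exp(beta[i])),
                ci_low=float(np.exp(beta[i] - zcrit * se[i])),
                ci_high=float(np.exp(beta[i] + zcrit * se[i])),
                p=float(2 * stats.norm.sf(np.abs(zstat[i])))
                if np.isfinite(zstat[i]) else np.nan))
    sigma2 = float(np.exp(2 * theta[-1]))
    if separation:
        warnings.warn("possible separation / degenerate outcome in GLMM")
    return GLMMResult(params=pd.DataFrame(rows).set_index("effect"),
                      sigma2_subject=sigma2,
                      converged=bool(res.success), separation_flag=separation,
                      loglik=-float(res.fun))


# ---------------------------------------------------------------------------
# linear mixed model of window pupil size

@dataclass
class LMMResult:
    params: pd.DataFrame          # beta, CI, p per fixed effect
    sigma2_subject: float
    sigma2_residual: float
    icc: float
    singular_flag: bool
    converged: bool


def icc(sigma2_subject: float, sigma2_residual: float) -> float:
    """Share of variance attributable to between-subject differences."""
    if sigma2_subject < 0 or sigma2_residual < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_subject + sigma2_residual
    if tot == 0:
        return float("nan")
    return sigma2_subject / tot


def fit_pupil_lmm(data: pd.DataFrame, formula: str,
                  groups: str = "subject", reml: bool = True) -> LMMResult:
    """Linear mixed model (subject random intercept) via statsmodels MixedLM.

    ``formula`` is a patsy fixed-effects formula for the trial-level
    window values, e.g. ``"value ~ C(condition)"``.
    """
    model = MixedLM.from_formula(formula, groups=data[groups], data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml)
    s2_subj = float(np.asarray(fit.cov_re)[0, 0])
    s2_resid = float(fit.scale)
    fe = fit.fe_params
    ci = fit.conf_int().loc[fe.index]
    params = pd.DataFrame({
        "beta": fe, "ci_low": ci[0], "ci_high": ci[1],
        "p": fit.pvalues.loc[fe.index]})
    singular = s2_subj < 1e-8 * max(s2_resid, 1e-12)
    return LMMResult(params=params, sigma2_subject=s2_subj,
                     sigma2_residual=s2_resid, icc=icc(s2_subj, s2_resid),
                     singular_flag=singular, converged=bool(fit.converged))
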