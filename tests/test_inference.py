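import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbpupil.inference import (fdr_bh, fit_pupil_lmm, fit_report_glmm, icc,
                               pointwise_paired_tests,
                               subject_condition_means, trial_window_values,
                               window_analysis, window_means)
from cbpupil.synth import simulate_report_table


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def brute_force_bh(p, q):
    """Independent step-up oracle: scan all k explicitly."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, bool)
    if k_star:
        mask[order[:k_star]] = True
    return mask


def test_bh_worked_example():
    mask = fdr_bh(np.array([0.01, 0.02, 0.04, 0.8]), q=0.05)
    assert list(mask) == [True, True, False, False]


def test_bh_all_ones_rejects_none():
    assert not fdr_bh(np.ones(20), q=0.05).any()


@settings(max_examples=250, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=60),
       st.floats(min_value=0.01, max_value=0.2))
def test_bh_equals_brute_force(p, q):
    np.testing.assert_array_equal(fdr_bh(np.array(p), q),
                                  brute_force_bh(p, q))


# ---------------------------------------------------------------------------
# pointwise paired tests

def _traces(n_sub, seed=0, offset=0.0):
    rng = np.random.default_rng(seed)
    times = -1 + np.arange(601) / 100
    data = rng.normal(size=(n_sub, 601)) + offset
    return pd.DataFrame(data, index=[f"s{i}" for i in range(n_sub)],
                        columns=times)


def test_identical_conditions_give_half_p_everywhere():
    a = _traces(8, seed=1)
    res = pointwise_paired_tests(a, a.copy(), sided="greater")
    assert len(res.time_s) == 501
    assert res.time_s[0] == pytest.approx(0.0)
    np.testing.assert_allclose(res.t_stat, 0.0, atol=1e-12)
    np.testing.assert_allclose(res.p_uncorrected, 0.5, atol=1e-12)
    assert not res.fdr_mask.any() and not res.uncorrected_mask.any()


def test_pairing_by_subject_key_not_position():
    a = _traces(10, seed=2)
    b = _traces(10, seed=3)
    res1 = pointwise_paired_tests(a, b)
    res2 = pointwise_paired_tests(a.sample(frac=1, random_state=0), b)
    np.testing.assert_allclose(res1.t_stat, res2.t_stat)


def test_fdr_mask_subset_of_uncorrected():
    a = _traces(12, seed=4, offset=0.3)
    b = _traces(12, seed=5)
    res = pointwise_paired_tests(a, b)
    assert not (res.fdr_mask & ~res.uncorrected_mask).any()


def test_two_sided_doubles_min_tail():
    a = _traces(9, seed=6, offset=0.5)
    b = _traces(9, seed=7)
    one = pointwise_paired_tests(a, b, sided="greater")
    two = pointwise_paired_tests(a, b, sided="two-sided")
    np.testing.assert_allclose(
        two.p_uncorrected,
        2 * np.minimum(one.p_uncorrected, 1 - one.p_uncorrected), atol=1e-12)


def test_too_few_subjects_errors():
    a = _traces(1)
    with pytest.raises(ValueError, match=">= 2 subjects"):
        pointwise_paired_tests(a, a)


# ---------------------------------------------------------------------------
# window analysis

def test_window_selects_samples_300_to_500(preprocessed):
    epoch_sets, trials = preprocessed
    ep = next(iter(epoch_sets.values()))
    sel = (ep.times >= 2.0 - 1e-9) & (ep.times <= 4.0 + 1e-9)
    assert sel.sum() == 201
    assert np.flatnonzero(sel)[0] == 300 and np.flatnonzero(sel)[-1] == 500


def test_window_analysis_zero_epochs(preprocessed):
    epoch_sets, trials = preprocessed
    zeroed = {}
    for s, ep in epoch_sets.items():
        import dataclasses
        zeroed[s] = dataclasses.replace(ep, data=np.zeros_like(ep.data))
    wm, tests = window_analysis(zeroed, trials)
    np.testing.assert_allclose(wm["value"], 0.0, atol=1e-12)
    est = tests[tests["estimable"]]
    assert set(est["p"].round(6)) <= {0.5, 1.0}


def test_window_analysis_baseline_normalized_base_is_zero(preprocessed):
    epoch_sets, trials = preprocessed
    wm = window_means(epoch_sets, trials)
    base = wm[wm["condition"] == "BASE"]
    np.testing.assert_allclose(base["value"], 0.0, atol=1e-12)


def test_condition_means_and_trial_values_consistent(preprocessed):
    epoch_sets, trials = preprocessed
    means = subject_condition_means(epoch_sets, trials)
    assert {"M", "NM", "BASE"} <= set(means)
    tv = trial_window_values(epoch_sets, trials)
    assert (tv.groupby("subject").size() <= 30).all()
    # per-subject M mean from trial values equals the window mean pre-normalization
    wm = window_means(epoch_sets, trials, baseline_normalize=False)
    for subj in tv["subject"].unique():
        a = tv[(tv.subject == subj) & (tv.condition == "M")
               & (tv.report_category != "EXCLUDED")]["value"].mean()
        b = wm[(wm.subject == subj) & (wm.condition == "M")]["value"].iloc[0]
        assert a == pytest.approx(b)


# ---------------------------------------------------------------------------
# logistic mixed model

def test_glmm_recovers_its_own_slopes_and_matches_lme4(tmp_path):
    """ML fit agrees with an independent lme4 fit on the same data."""
    df = simulate_report_table(80, seed=9)
    res = fit_report_glmm(df, fixed=("m_order", "confidence", "dissimilar"))
    assert res.converged and not res.separation_flag

    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = shutil.which("Rscript")
    assert rscript, "Rscript expected on PATH"
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(outcome ~ m_order + confidence + dissimilar + (1|subject),
                   data=d, family=binomial, nAGQ=25)
        co <- summary(m)$coefficients
        write.csv(data.frame(effect=rownames(co), beta=co[,1], se=co[,2]),
                  "{tmp_path}/out.csv", row.names=FALSE)
    """))
    subprocess.run([rscript, str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.csv").set_index("effect")
    for mine, theirs in [("intercept", "(Intercept)"), ("m_order", "m_order"),
                         ("confidence", "confidence"),
                         ("dissimilar", "dissimilar")]:
        assert res.params.loc[mine, "beta"] == pytest.approx(
            ref.loc[theirs, "beta"], abs=0.02)
        assert res.params.loc[mine, "se"] == pytest.approx(
            ref.loc[theirs, "se"], abs=0.02)


def test_glmm_flags_degenerate_outcome():
    df = simulate_report_table(30, seed=2)
    df["outcome"] = 1
    with pytest.warns(UserWarning, match="separation"):
        res = fit_report_glmm(df, fixed=("m_order",))
    assert res.separation_flag


def test_glmm_null_ci_covers_one():
    """With outcomes independent of the covariate, the slope's 95% CI
    should cover OR = 1 at roughly the nominal rate."""
    rng = np.random.default_rng(17)
    covered = 0
    reps = 60
    for rep in range(reps):
        df = simulate_report_table(40, b_trial=0.0, b_conf=0.0, b_dissim=0.0,
                                   seed=int(rng.integers(2 ** 31)))
        res = fit_report_glmm(df, fixed=("m_order",))
        lo, hi = res.params.loc["m_order", ["ci_low", "ci_high"]]
        covered += lo <= 1.0 <= hi
    assert covered / reps >= 0.85


# ---------------------------------------------------------------------------
# linear mixed model / ICC

def test_icc_arithmetic():
    assert icc(0.2, 0.6) == pytest.approx(0.25)
    assert icc(0.0, 1.3) == 0.0
    assert icc(0.7, 0.0) == 1.0
    assert math.isnan(icc(0.0, 0.0))
    with pytest.raises(ValueError):
        icc(-0.1, 0.5)


def test_lmm_fixed_effect_and_icc_recovery():
    rng = np.random.default_rng(23)
    nsub, ntr = 120, 16
    u = rng.normal(0, np.sqrt(0.2), nsub)
    cond = np.tile([0] * 8 + [1] * 8, nsub)
    subj = np.repeat(np.arange(nsub), ntr)
    y = u[subj] + 0.576 * cond + rng.normal(0, np.sqrt(0.6), nsub * ntr)
    df = pd.DataFrame(dict(subject=subj, is_m=cond, value=y))
    res = fit_pupil_lmm(df, "value ~ is_m")
    lo, hi = res.params.loc["is_m", ["ci_low", "ci_high"]]
    assert lo <= 0.576 <= hi
    assert res.icc == pytest.approx(0.25, abs=0.08)
    assert not res.singular_flag


def test_lmm_zero_between_subject_variance_flags_singular():
    rng = np.random.default_rng(31)
    df = pd.DataFrame(dict(subject=np.repeat(np.arange(40), 10),
                           value=rng.normal(size=400)))
    res = fit_pupil_lmm(df, "value ~ 1")
    assert res.icc < 0.05
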