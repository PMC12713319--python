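"""Synthetic choice-blindness cohorts: behavior, pupil traces, ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without real recordings:

* 30-trial sessions with 8 manipulated (M) trials at fixed positions, 8
  non-manipulated (NM) trials at random positions and 14 baseline trials;
  deterministic within-trial timing (ratings and report phases get fixed
  nominal durations, so test-image onsets are reproducible).
* Subject-level reporting phenotypes (all-report / some-report /
  no-report) with detection probability rising with M-trial order,
  confidence and pair dissimilarity, and concurrent reporting conditional
  on detection.  Retrospective identification is conditional on detection,
  with a memorability offset distinguishing colored-photograph-like from
  monochrome-face-like stimuli, plus independent false positives on non-M
  pairs.  The generator never produces a report without detection.
* Continuous 1000 Hz pupil traces: subject baseline + band-limited
  random-walk drift + event-related responses (unit impulses at test-image
  onsets scaled by condition/detection-dependent amplitudes, convolved
  with the canonical kernel) + white noise, with Poisson blinks (pupil
  forced to the missing sentinel with 50 ms cosine ramps) and small
  biphasic saccade transients.

Amplitudes and noise levels are free parameters, loosely calibrated so
that cohort-level summaries resemble the study conditions; they are not
estimates of any real quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .config import ExperimentConfig
from .datatypes import PupilRecording, make_event_table, validate_trial_table
from .preprocess import IRFParams, pupil_irf

PHENOTYPES = ("all_report", "some_report", "no_report")


@dataclass
class BehaviorParams:
    """Generative model for detection and reporting.

    Detection on M-trials is Bernoulli with logit
    ``b0 + b_trial*order + b_conf*confidence + b_dissim*[dissimilar]``
    (order = M-trial number 1..8).  Concurrent report given detection
    depends on the subject's phenotype; retrospective report given
    detection is logistic in ``m0 + m_mem`` where the memorability offset
    is high for colored-photograph-like stimuli and low for
    monochrome-face-like ones.  Phenotype shares default to the observed
    group sizes 8/41, 23/41, 10/41.
    """

    phenotype_probs: tuple[float, float, float] = (8 / 41, 23 / 41, 10 / 41)
    detect_b0: float = 0.0
    detect_b_trial: float = 0.25
    detect_b_conf: float = 0.15
    detect_b_dissim: float = 0.8
    report_all_p: float = 0.98
    report_none_p: float = 0.02
    report_some_b0: float = -1.2
    report_some_b_trial: float = 0.45
    possible_given_unreported: float = 0.05
    retro_m0: float = 0.0
    retro_m_mem: float = 2.2          # exp1-like default; exp2-like ~ -0.2
    retro_false_positive_rate: float = 0.033

    def __post_init__(self) -> None:
        p = np.asarray(self.phenotype_probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("phenotype_probs must be a probability vector")


@dataclass
class PupilGenParams:
    """Generative model for the continuous pupil trace (arbitrary units)."""

    baseline_mean: float = 3000.0
    baseline_sd: float = 300.0
    drift_sd: float = 8.0            # random-walk scale per sqrt(s), band-limited
    noise_sd: float = 15.0
    amp_base: float = 30.0           # response to any expected test image
    amp_delta_detect: float = 30.0   # extra amplitude on detected M-trials
    amp_delta_undetect: float = 0.0
    irf: IRFParams = field(default_factory=IRFParams)
    blink_rate_hz: float = 0.25
    blink_dur_mu: float = float(np.log(0.120))  # lognormal, median 120 ms
    blink_dur_sigma: float = 0.4
    saccade_rate_hz: float = 1.5

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "drift_sd", "noise_sd",
                     "blink_rate_hz", "saccade_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# schedule and behavior

def make_schedule(config: ExperimentConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial skeleton: conditions at positions, onsets, pair ids, similarity."""
    cond = np.array(["BASE"] * config.n_trials, dtype=object)
    mpos = np.asarray(config.m_trial_positions) - 1
    cond[mpos] = "M"
    rest = np.setdiff1d(np.arange(config.n_trials), mpos)
    nm = rng.choice(rest, size=config.n_nm_trials, replace=False)
    cond[nm] = "NM"

    # dissimilarity class of each M-pair (similar vs dissimilar esthetic rating)
    sim = np.array(["similar"] * config.n_similar_pairs
                   + ["dissimilar"] * config.n_dissimilar_pairs, dtype=object)
    rng.shuffle(sim)

    rows = []
    t = 0.0
    m_order = 0
    for i in range(config.n_trials):
        c = cond[i]
        onset = t + config.test_onset_offset_s(c)
        similarity = ""
        if c == "M":
            similarity = sim[m_order]
            m_order += 1
        rows.append(dict(trial_idx=i + 1, condition=c, pair_id=f"pair{i + 1:02d}",
                         similarity=similarity, test_onset_s=onset))
        t += config.trial_duration_s(c)
    df = pd.DataFrame(rows)
    df.attrs["session_duration_s"] = t
    return df


def generate_behavior(phenotype: str, params: BehaviorParams,
                      trials: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Fill ratings, detection, concurrent/retrospective reports for one subject.

    ``trials`` is a schedule from :func:`make_schedule`; returns a full
    trial table plus ground-truth columns (``detected``, ``amp_group``).
    """
    df = trials.copy()
    n = len(df)
    is_rep = df["condition"].isin(("M", "NM")).to_numpy()
    conf = np.clip(np.rint(rng.normal(6.0, 1.8, size=n)), 1, 9).astype(int)
    rating = np.clip(np.rint(rng.normal(1.0, 2.0, size=n)), -4, 4).astype(int)
    df["confidence"] = np.where(is_rep, conf, 0)
    df["esthetic_rating"] = np.where(is_rep, rating, 0)

    detected = np.zeros(n, dtype=bool)
    code = np.array(["" for _ in range(n)], dtype=object)
    retro = np.zeros(n, dtype=bool)
    retro_fp = np.zeros(n, dtype=bool)

    m_rows = np.flatnonzero((df["condition"] == "M").to_numpy())
    for order, i in enumerate(m_rows, start=1):
        z = (params.detect_b0 + params.detect_b_trial * order
             + params.detect_b_conf * df["confidence"].iloc[i]
             + params.detect_b_dissim * (df["similarity"].iloc[i] == "dissimilar"))
        detected[i] = rng.random() < _logistic(z)
        if detected[i]:
            if phenotype == "all_report":
                p_rep = params.report_all_p
            elif phenotype == "no_report":
                p_rep = params.report_none_p
            else:
                p_rep = _logistic(params.report_some_b0
                                  + params.report_some_b_trial * order)
            if rng.random() < p_rep:
                code[i] = "report"
            elif rng.random() < params.possible_given_unreported:
                code[i] = "possible"
            else:
                code[i] = "none"
            retro[i] = rng.random() < _logistic(params.retro_m0 + params.retro_m_mem)
        else:
            code[i] = "none"

    nonm = ~(df["condition"] == "M").to_numpy()
    retro_fp[nonm] = rng.random(nonm.sum()) < params.retro_false_positive_rate
    df["concurrent_code"] = code
    df.loc[~is_rep, "concurrent_code"] = ""
    df.loc[is_rep & nonm, "concurrent_code"] = "none"
    df["retrospective_flag"] = retro
    df["retro_false_positive_flag"] = retro_fp
    df["detected"] = detected
    df["phenotype"] = phenotype
    return df


# ---------------------------------------------------------------------------
# pupil trace

def _blink_envelope(n: int, rate: float, intervals: np.ndarray) -> np.ndarray:
    """Multiplicative envelope: 0 inside blinks, 50 ms cosine ramps outside."""
    env = np.ones(n)
    ramp = int(round(0.050 * rate))
    up = 0.5 * (1 + np.cos(np.linspace(0, np.pi, ramp, endpoint=False)))
    for s_ms, e_ms in intervals:
        i0 = int(round(s_ms / 1000.0 * rate))
        i1 = int(round(e_ms / 1000.0 * rate))
        env[max(i0, 0):min(i1, n)] = 0.0
        a = max(i0 - ramp, 0)
        env[a:i0] = np.minimum(env[a:i0], up[ramp - (i0 - a):])
        b = min(i1 + ramp, n)
        env[i1:b] = np.minimum(env[i1:b], up[::-1][:b - i1])
    return env


def generate_pupil_trace(trials: pd.DataFrame, detected: np.ndarray,
                         config: ExperimentConfig, params: PupilGenParams,
                         rng: np.random.Generator
                         ) -> tuple[PupilRecording, pd.DataFrame, np.ndarray]:
    """Continuous trace + event table + per-trial injected amplitudes."""
    rate = config.sample_rate_hz
    T = float(trials.attrs.get("session_duration_s",
                               trials["test_onset_s"].iloc[-1]
                               + config.trial_duration_s(trials["condition"].iloc[-1])))
    n = int(round(T * rate))
    t = np.arange(n) / rate

    amps = np.full(len(trials), params.amp_base, dtype=float)
    is_m = (trials["condition"] == "M").to_numpy()
    amps[is_m & detected] += params.amp_delta_detect
    amps[is_m & ~detected] += params.amp_delta_undetect

    train = np.zeros(n)
    onset_idx = np.rint(trials["test_onset_s"].to_numpy() * rate).astype(int)
    np.add.at(train, onset_idx, amps)
    kernel = pupil_irf(params.irf, rate)
    signal = fftconvolve(train, kernel)[:n]

    sig = signal + rng.normal(params.baseline_mean, params.baseline_sd)
    if params.drift_sd > 0:
        # band-limited random walk: generated at 10 Hz, cubic-smoothly
        # interpolated to the native rate (spectrum confined below ~5 Hz)
        drift_rate = 10.0
        n_lo = int(np.ceil(T * drift_rate)) + 2
        walk = np.cumsum(rng.normal(0.0, params.drift_sd / np.sqrt(drift_rate),
                                    size=n_lo))
        sig = sig + np.interp(t, np.arange(n_lo) / drift_rate, walk)
    if params.noise_sd > 0:
        noise = rng.normal(0.0, params.noise_sd, size=n)
    else:
        noise = 0.0

    # saccades: small biphasic transients, logged as 40 ms events
    sac_n = rng.poisson(params.saccade_rate_hz * T)
    sac_t = np.sort(rng.uniform(0.05, T - 0.15, size=sac_n))
    if len(sac_t) > 1:  # enforce separation so logged events never overlap
        keep = np.concatenate([[True], np.diff(sac_t) > 0.045])
        sac_t = sac_t[keep]
    sac_n = len(sac_t)
    sac_kernel_t = np.arange(0, 0.1, 1 / rate)
    sac_kernel = (0.1 * params.noise_sd * np.sin(2 * np.pi * sac_kernel_t / 0.1)
                  * np.hanning(len(sac_kernel_t)))
    sac_train = np.zeros(n)
    np.add.at(sac_train, np.rint(sac_t * rate).astype(int), 1.0)
    sig = sig + noise + fftconvolve(sac_train, sac_kernel)[:n]

    # blinks: Poisson times, lognormal durations, pupil -> 0 and invalid
    bl_n = rng.poisson(params.blink_rate_hz * T)
    bl_t = np.sort(rng.uniform(0.2, T - 1.0, size=bl_n))
    bl_d = rng.lognormal(params.blink_dur_mu, params.blink_dur_sigma, size=bl_n)
    bl_iv = np.stack([np.rint(bl_t * 1000).astype(np.int64),
                      np.rint((bl_t + bl_d) * 1000).astype(np.int64)], axis=1) \
        if bl_n else np.empty((0, 2), dtype=np.int64)
    from .datatypes import merge_intervals
    bl_iv = merge_intervals(bl_iv)

    valid = np.ones(n, dtype=bool)
    if len(bl_iv):
        sig = sig * _blink_envelope(n, rate, bl_iv)
        t_ms = np.rint(t * 1000).astype(np.int64)
        for s, e in bl_iv:
            m = (t_ms >= s) & (t_ms < e)
            sig[m] = 0.0
            valid[m] = False

    kinds = ["blink"] * len(bl_iv) + ["saccade"] * sac_n
    starts = list(bl_iv[:, 0]) + list(np.rint(sac_t * 1000).astype(np.int64))
    ends = list(bl_iv[:, 1]) + list(np.rint((sac_t + 0.040) * 1000).astype(np.int64))
    events = make_event_table(kinds, starts, ends)

    rec = PupilRecording(t=t, pupil=sig, rate=rate, valid=valid)
    return rec, events, amps


# ---------------------------------------------------------------------------
# cohort

@dataclass
class SubjectData:
    subject: str
    recording: PupilRecording
    events: pd.DataFrame
    trials: pd.DataFrame


def generate_subject(subject: str, config: ExperimentConfig,
                     behavior: BehaviorParams, pupil: PupilGenParams | None,
                     rng: np.random.Generator) -> tuple[SubjectData, pd.DataFrame]:
    """One subject's session; returns data + ground-truth rows."""
    phenotype = PHENOTYPES[rng.choice(3, p=np.asarray(behavior.phenotype_probs))]
    sched = make_schedule(config, rng)
    trials = generate_behavior(phenotype, behavior, sched, rng)
    detected = trials["detected"].to_numpy()

    if pupil is not None:
        rec, events, amps = generate_pupil_trace(trials, detected, config,
                                                 pupil, rng)
    else:
        rec, events, amps = None, make_event_table([], [], []), np.zeros(len(trials))

    truth = trials[["trial_idx", "condition", "similarity", "detected",
                    "phenotype"]].copy()
    truth.insert(0, "subject", subject)
    truth["reported_concurrent"] = trials["concurrent_code"] == "report"
    truth["reported_retro"] = trials["retrospective_flag"]
    truth["amp"] = amps

    public = trials.drop(columns=["detected", "phenotype"])
    validate_trial_table(public, config)
    data = SubjectData(subject=subject, recording=rec, events=events,
                       trials=public)
    return data, truth


def generate_cohort(config: ExperimentConfig,
                    behavior: BehaviorParams | None = None,
                    pupil: PupilGenParams | None = None,
                    n_subjects: int = 41,
                    seed: int = 0,
                    with_pupil: bool = True
                    ) -> tuple[list[SubjectData], pd.DataFrame]:
    """Deterministic cohort for a fixed seed.

    Returns per-subject data and a pooled ground-truth table.  With
    ``with_pupil=False`` only behavior is generated (fast path for
    behavioral Monte-Carlo checks).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    behavior = behavior or BehaviorParams()
    if with_pupil:
        pupil = pupil or PupilGenParams()
    else:
        pupil = None
    ss = np.random.SeedSequence(seed)
    subjects, truths = [], []
    for i, child in enumerate(ss.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        sd, truth = generate_subject(f"s{i:03d}", config, behavior, pupil, rng)
        subjects.append(sd)
        truths.append(truth)
    return subjects, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# direct logistic simulation for mixed-model recovery checks

def simulate_report_table(n_subjects: int, *, b0: float = -1.0,
                          b_trial: float = float(np.log(1.9)),
                          b_conf: float = 0.2, b_dissim: float = 0.5,
                          sigma_subject: float = 0.7,
                          seed: int = 0) -> pd.DataFrame:
    """M-trial report outcomes from an exactly specified logistic GLMM.

    Outcome ~ Bernoulli(logistic(b0 + b_trial*order + b_conf*conf
    + b_dissim*dissim + u_subject)), u ~ N(0, sigma_subject^2).  Used to
    verify that the report model recovers its own generating parameters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0.0, sigma_subject)
        conf = np.clip(np.rint(rng.normal(6.0, 1.8, size=8)), 1, 9)
        dissim = rng.permutation([0, 0, 0, 0, 1, 1, 1, 1])
        order = np.arange(1, 9)
        z = b0 + b_trial * order + b_conf * conf + b_dissim * dissim + u
        y = rng.random(8) < _logistic(z)
        for k in range(8):
            rows.append(dict(subject=f"s{s:04d}", m_order=order[k],
                             confidence=conf[k], dissimilar=dissim[k],
                             outcome=int(y[k])))
    return pd.DataFrame(rows)
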