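"""Shared in-memory containers for recordings, events, trials and epochs.

Conventions
-----------
* Time is seconds (float) internally; event boundaries are integer
  milliseconds with the half-open interval convention [start_ms, end_ms):
  a sample at time t belongs to an event iff start_ms <= 1000*t < end_ms.
* Missing pupil data is carried in the boolean validity mask, never as NaN
  past the interpolation stage.
* Each preprocessing stage stamps ``stage_tag`` and refuses out-of-order
  input; the canonical order is listed in ``STAGE_ORDER``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGE_ORDER = (
    "raw",
    "interpolated",
    "filtered",
    "standardized",
    "downsampled",
    "nuisance_regressed",
)

TRIAL_COLUMNS = (
    "trial_idx", "condition", "pair_id", "similarity", "confidence",
    "esthetic_rating", "test_onset_s", "concurrent_code",
    "retrospective_flag", "retro_false_positive_flag",
)

CONDITIONS = ("M", "NM", "BASE")
CONCURRENT_CODES = ("report", "possible", "none")


@dataclass
class PupilRecording:
    """Continuous monocular pupil samples for one session."""

    t: np.ndarray          # seconds since session start
    pupil: np.ndarray      # a.u. (raw) or z-units (after standardization)
    rate: float            # Hz
    valid: np.ndarray      # per-sample, False = missing / blink-flagged
    gaze_x: np.ndarray | None = None
    gaze_y: np.ndarray | None = None
    stage_tag: str = "raw"
    units: str = "au"
    # set by standardize(): a.u. per z-unit, so raw = pupil * scale
    scale: float | None = None
    # set by downsample(): the native-rate validity mask and rate, needed to
    # compute per-epoch invalid fractions at acquisition resolution
    native_valid: np.ndarray | None = None
    native_rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.pupil) == len(self.valid)):
            raise ValueError("t, pupil and valid must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("non-monotone time")
        if len(dt) and not np.allclose(dt, 1.0 / self.rate, atol=1e-6):
            raise ValueError("sampling step inconsistent with declared rate")

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "PupilRecording":
        return PupilRecording(
            t=self.t.copy(), pupil=self.pupil.copy(), rate=self.rate,
            valid=self.valid.copy(),
            gaze_x=None if self.gaze_x is None else np.asarray(self.gaze_x).copy(),
            gaze_y=None if self.gaze_y is None else np.asarray(self.gaze_y).copy(),
            stage_tag=self.stage_tag, units=self.units, scale=self.scale,
            native_valid=None if self.native_valid is None else self.native_valid.copy(),
            native_rate=self.native_rate,
        )

    def require_stage(self, expected: str) -> None:
        if self.stage_tag != expected:
            raise ValueError(
                f"pipeline order violation: expected stage {expected!r}, "
                f"got {self.stage_tag!r}"
            )


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/touching [start, end) integer-ms intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0])]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def make_event_table(kind, start_ms, end_ms, *, merge: bool = True) -> pd.DataFrame:
    """Validated blink/saccade event table; merges same-kind overlaps."""
    df = pd.DataFrame({
        "kind": pd.Series(kind, dtype=str),
        "start_ms": pd.Series(start_ms, dtype=np.int64),
        "end_ms": pd.Series(end_ms, dtype=np.int64),
    })
    bad = df["kind"].isin(("blink", "saccade"))
    if not bad.all():
        raise ValueError(f"unknown event kinds: {sorted(df.loc[~bad, 'kind'].unique())}")
    if (df["end_ms"] <= df["start_ms"]).any():
        raise ValueError("event intervals must satisfy end > start")
    pieces = []
    for k, grp in df.groupby("kind", sort=True):
        iv = grp[["start_ms", "end_ms"]].to_numpy()
        merged = merge_intervals(iv)
        if merge and len(merged) < len(iv):
            warnings.warn(f"merged {len(iv) - len(merged)} overlapping {k} events")
        pieces.append(pd.DataFrame(
            {"kind": k, "start_ms": merged[:, 0], "end_ms": merged[:, 1]}))
    if not pieces:
        return pd.DataFrame({"kind": pd.Series(dtype=str),
                             "start_ms": pd.Series(dtype=np.int64),
                             "end_ms": pd.Series(dtype=np.int64)})
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["start_ms", "kind"], ignore_index=True)


def validate_trial_table(trials: pd.DataFrame, config) -> pd.DataFrame:
    """Schema- and invariant-check a trial table against a config."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    counts = trials["condition"].value_counts()
    expect = {"M": config.n_m_trials, "NM": config.n_nm_trials,
              "BASE": config.n_baseline_trials}
    for cond, n in expect.items():
        if int(counts.get(cond, 0)) != n:
            raise ValueError(
                f"condition counts inconsistent with config: {cond} "
                f"has {int(counts.get(cond, 0))}, expected {n}")
    m_idx = sorted(trials.loc[trials["condition"] == "M", "trial_idx"])
    if tuple(m_idx) != tuple(config.m_trial_positions):
        raise ValueError("M-trials are not at the configured positions")
    onsets = trials.sort_values("trial_idx")["test_onset_s"].to_numpy()
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("test_onset_s must increase with trial_idx")
    rep = trials["condition"].isin(("M", "NM"))
    if not trials.loc[rep, "concurrent_code"].isin(CONCURRENT_CODES).all():
        raise ValueError("invalid concurrent_code on report trials")
    conf = trials.loc[rep, "confidence"]
    if ((conf < 1) | (conf > 9)).any():
        raise ValueError("confidence out of 1..9")
    rating = trials.loc[rep, "esthetic_rating"]
    if ((rating < -4) | (rating > 4)).any():
        raise ValueError("esthetic_rating out of -4..4")
    return trials


@dataclass
class EpochSet:
    """Trials x timepoints matrix of preprocessed pupil around test onset.

    ``data`` is in z-units on the window given by ``times`` (default -1..5 s
    at 100 Hz, 601 samples; sample k lies at -1 + k/100 s), baseline-mean
    subtracted per trial over [-1, 0) s.  ``invalid_fraction`` is computed
    from the native-rate validity mask over the same window.  ``included``
    is set by QC: a trial is retained iff its invalid fraction does not
    exceed one third of the window.
    """

    data: np.ndarray              # (n_trials, n_timepoints)
    times: np.ndarray             # (n_timepoints,)
    trial_keys: np.ndarray        # trial_idx per row
    invalid_fraction: np.ndarray  # (n_trials,)
    included: np.ndarray          # bool per trial
    rate: float
    session_scale: float | None = None   # a.u. per z-unit, from standardize()
    subject: str | None = None

    def __post_init__(self) -> None:
        n, m = self.data.shape
        if not (len(self.times) == m and len(self.trial_keys) == n
                and len(self.invalid_fraction) == n and len(self.included) == n):
            raise ValueError("inconsistent EpochSet shapes")
        if np.any((self.invalid_fraction < 0) | (self.invalid_fraction > 1)):
            raise ValueError("invalid_fraction out of [0,1]")
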