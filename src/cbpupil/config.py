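"""Experiment configuration: trial schedule, timing, and preprocessing constants.

The session structure mirrors a computerized choice-blindness experiment:
30 trials per subject, of which 8 are manipulated (M) trials at fixed
positions, 8 are non-manipulated (NM) trials at random positions, and 14
are baseline trials (selection + fixation + test image only, no report
phase).  Timing constants drive both the synthetic generator and the
epoching/QC stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

DEFAULT_M_POSITIONS = (7, 10, 14, 16, 20, 22, 26, 29)


@dataclass
class ExperimentConfig:
    """All schedule, timing and preprocessing parameters for one profile.

    Times are seconds; sampling rates are Hz.  ``m_trial_positions`` are
    1-based trial indices.  The filter band and epoch/analysis windows
    follow the standard event-related pupillometry pipeline: 0.02-4 Hz
    third-order Butterworth band-pass, epochs from -1 to 5 s around test
    image onset at 100 Hz, window statistics over 2-4 s.
    """

    n_trials: int = 30
    m_trial_positions: tuple[int, ...] = DEFAULT_M_POSITIONS
    n_nm_trials: int = 8
    n_baseline_trials: int = 14
    pair_presentation_s: float = 3.0
    rating_s: float = 4.0
    fixation_s: float = 2.5
    test_image_s: float = 5.0
    report_s: float = 6.0
    iti_s: float = 2.0
    sample_rate_hz: float = 1000.0
    target_rate_hz: float = 100.0
    epoch_window_s: tuple[float, float] = (-1.0, 5.0)
    analysis_window_s: tuple[float, float] = (2.0, 4.0)
    filter_band_hz: tuple[float, float] = (0.02, 4.0)
    filter_order: int = 3
    blink_pad_ms: int = 150
    fdr_q: float = 0.05
    # number of M-pairs in each similarity class (similar, dissimilar)
    n_similar_pairs: int = 4
    n_dissimilar_pairs: int = 4
    profile: str = "exp1"

    def __post_init__(self) -> None:
        mpos = tuple(int(p) for p in self.m_trial_positions)
        object.__setattr__(self, "m_trial_positions", mpos)
        if any(b <= a for a, b in zip(mpos, mpos[1:])):
            raise ValueError("m_trial_positions must be strictly increasing")
        if mpos and (mpos[0] < 1 or mpos[-1] > self.n_trials):
            raise ValueError("m_trial_positions must lie within 1..n_trials")
        n_m = len(mpos)
        if n_m + self.n_nm_trials + self.n_baseline_trials != self.n_trials:
            raise ValueError(
                f"condition counts {n_m}+{self.n_nm_trials}+{self.n_baseline_trials} "
                f"do not sum to n_trials={self.n_trials}"
            )
        lo, hi = self.epoch_window_s
        alo, ahi = self.analysis_window_s
        if not (lo <= alo < ahi <= hi):
            raise ValueError("epoch window must contain analysis window")
        flo, fhi = self.filter_band_hz
        if not (0.0 < flo < fhi < self.sample_rate_hz / 2.0):
            raise ValueError("filter band must satisfy 0 < low < high < Nyquist")
        if self.n_similar_pairs + self.n_dissimilar_pairs != n_m:
            raise ValueError("similarity pair counts must sum to the M-trial count")

    @property
    def n_m_trials(self) -> int:
        return len(self.m_trial_positions)

    def trial_duration_s(self, condition: str) -> float:
        """Total duration of one trial of the given condition."""
        if condition in ("M", "NM"):
            return (self.pair_presentation_s + self.rating_s + self.fixation_s
                    + self.test_image_s + self.report_s + self.iti_s)
        if condition == "BASE":
            return (self.pair_presentation_s + self.fixation_s
                    + self.test_image_s + self.iti_s)
        raise ValueError(f"unknown condition {condition!r}")

    def test_onset_offset_s(self, condition: str) -> float:
        """Offset of test-image onset from trial start."""
        if condition in ("M", "NM"):
            return self.pair_presentation_s + self.rating_s + self.fixation_s
        if condition == "BASE":
            return self.pair_presentation_s + self.fixation_s
        raise ValueError(f"unknown condition {condition!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("m_trial_positions", "epoch_window_s", "analysis_window_s",
                  "filter_band_hz"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("m_trial_positions", "epoch_window_s", "analysis_window_s",
                  "filter_band_hz"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def exp1_config(**overrides) -> ExperimentConfig:
    """Colored-photograph profile: 3 s pair presentation."""
    return ExperimentConfig(profile="exp1", pair_presentation_s=3.0, **overrides)


def exp2_config(**overrides) -> ExperimentConfig:
    """Monochrome-face profile: 5 s pair presentation."""
    return ExperimentConfig(profile="exp2", pair_presentation_s=5.0, **overrides)
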