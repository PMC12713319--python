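import warnings

import numpy as np
import pytest

from cbpupil.config import exp1_config
from cbpupil.preprocess import preprocess_session
from cbpupil.synth import BehaviorParams, PupilGenParams, generate_cohort


@pytest.fixture(scope="session")
def cfg():
    return exp1_config()


@pytest.fixture(scope="session")
def small_cohort(cfg):
    """Four subjects with full pupil traces, default study conditions."""
    subjects, truth = generate_cohort(cfg, n_subjects=4, seed=11)
    return subjects, truth


@pytest.fixture(scope="session")
def preprocessed(cfg, small_cohort):
    """Epoch sets and trial tables keyed by subject for the small cohort."""
    subjects, truth = small_cohort
    epoch_sets, trials_by_subject = {}, {}
    for sd in subjects:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep, verdict = preprocess_session(sd.recording, sd.events,
                                             sd.trials, cfg,
                                             subject=sd.subject)
        if not verdict.subject_excluded:
            epoch_sets[sd.subject] = ep
            trials_by_subject[sd.subject] = sd.trials
    return epoch_sets, trials_by_subject


@pytest.fixture(scope="session")
def noise_free_cohort(cfg):
    """Deterministic cohort: unit-amplitude detected-M responses only."""
    bp = BehaviorParams(detect_b0=50.0)   # saturates detection
    pp = PupilGenParams(baseline_sd=0.0, drift_sd=0.0, noise_sd=0.0,
                        amp_base=0.0, amp_delta_detect=1.0,
                        blink_rate_hz=0.0, saccade_rate_hz=0.0)
    subjects, truth = generate_cohort(cfg, bp, pp, n_subjects=3, seed=5)
    return subjects, truth
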