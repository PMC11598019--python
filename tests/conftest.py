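import numpy as np
import pytest

from semgnet.io_emg import EmgRecording
from semgnet.synth import SyntheticConfig, simulate_cohort
from semgnet.preprocess import (FilterSpec, apply_normalization,
                                bandpass_notch, concat_window_sets,
                                fit_normalization, window_signal)
from semgnet.protocol import holdout_tl_subjects, make_intra_subject_split


def tiny_recording(n_gestures=2, n_reps=3, run_len=40, rest_len=10,
                   n_channels=4, fs=100.0, subject_id="S00", seed=0):
    """Hand-assembled recording with a known gesture/rest schedule."""
    rng = np.random.default_rng(seed)
    emg, stim, rep = [], [], []
    for g in range(1, n_gestures + 1):
        for r in range(1, n_reps + 1):
            emg.append(rng.standard_normal((rest_len, n_channels)))
            stim.append(np.zeros(rest_len, dtype=np.int64))
            rep.append(np.zeros(rest_len, dtype=np.int64))
            emg.append(rng.standard_normal((run_len, n_channels)) * g)
            stim.append(np.full(run_len, g, dtype=np.int64))
            rep.append(np.full(run_len, r, dtype=np.int64))
    rec = EmgRecording(emg=np.concatenate(emg), fs=fs,
                       stimulus=np.concatenate(stim),
                       repetition=np.concatenate(rep),
                       subject_id=subject_id)
    rec.validate()
    return rec


@pytest.fixture
def tiny_rec():
    return tiny_recording()


def small_cohort_cfg(seed=1, **overrides):
    """Reduced cohort used in training tests: short recordings at 500 Hz."""
    base = dict(n_subjects=6, n_amputees=1, n_gestures=4, n_repetitions=6,
                fs=500.0, gesture_duration_s=0.4, rest_duration_s=0.3,
                subject_gain_sd=0.35, electrode_shift_max=1, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


def preprocessed_sets(cfg, window_ms=120.0, method="zscore", scope="subject"):
    """cohort → filter → normalize (train reps) → per-subject WindowSets."""
    recs = simulate_cohort(cfg)
    recs = [bandpass_notch(r, FilterSpec()) for r in recs]
    stats = fit_normalization(recs, method, scope, repetitions={2, 4, 6})
    recs = [apply_normalization(r, stats[r.subject_id]) for r in recs]
    flags = {r.subject_id: r.amputee for r in recs}
    return {r.subject_id: window_signal(r, window_ms, 0.75) for r in recs}, flags


def build_study(seed, n_subjects=11, n_amputees=1, gain_sd=0.35, shift=1,
                n_hold_healthy=2, n_hold_amputee=1):
    """Cohort → preprocessing → holdout → intra-subject split → pool."""
    cfg = small_cohort_cfg(seed=seed, n_subjects=n_subjects,
                           n_amputees=n_amputees, subject_gain_sd=gain_sd,
                           electrode_shift_max=shift)
    sets, flags = preprocessed_sets(cfg)
    subjects = sorted(sets)
    holdout, remainder = holdout_tl_subjects(
        subjects, [flags[s] for s in subjects],
        n_hold_healthy, n_hold_amputee, seed=seed)
    split = make_intra_subject_split(remainder, holdout_subjects=holdout,
                                     seed=seed)
    pool = concat_window_sets([sets[s] for s in remainder])
    return sets, flags, holdout, split, pool
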