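"""Synthetic multi-subject sEMG cohorts.

The generator emulates the statistical structure the pipeline relies on,
without modelling motor-unit physiology:

* per-gesture spatial activation patterns, smooth over the 8-electrode
  forearm ring (so circular padding is meaningful) plus free weights on the
  remaining electrodes;
* an amplitude-modulated carrier of band-limited Gaussian noise with its
  power concentrated in the 20–150 Hz band that dominates surface EMG;
* subject-specific multiplicative per-channel gains and an optional integer
  rotation of the ring (electrode donning shift) — the between-subject
  covariate shift that normalisation and domain-adversarial pre-training
  are meant to absorb;
* additive 50 Hz line interference and a white noise floor;
* a mild repetition-indexed amplitude decline as a muscular-fatigue proxy;
* "amputee-like" subjects with attenuated activation and larger
  gain/shift perturbations.

Amplitudes are scaled to the ±5000 μV physiological range of surface EMG.
Everything is deterministic given ``(seed, subject_index)``; per-subject
RNG substreams are keyed independently so adding subjects to a cohort does
not reshuffle earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import scipy.signal

from .io_emg import EmgRecording

__all__ = ["SyntheticConfig", "simulate_subject", "simulate_cohort"]

_PEAK_UV = 2000.0        # active-segment template peak, μV
_FATIGUE_SLOPE = 0.04    # fractional amplitude loss per repetition
_AMPUTEE_ATTENUATION = 0.6


@dataclass
class SyntheticConfig:
    n_subjects: int = 15
    n_amputees: int = 3
    n_gestures: int = 14
    n_repetitions: int = 6
    fs: float = 2000.0
    gesture_duration_s: float = 5.0
    rest_duration_s: float = 3.0
    n_channels: int = 12
    ring_channels: int = 8
    subject_gain_sd: float = 0.25     # log-scale sd of per-channel gains
    electrode_shift_max: int = 1      # max |ring rotation| in channels
    line_interference_amp: float = 0.05  # relative to template peak
    noise_floor: float = 0.05            # relative to template peak
    seed: int = 0

    def validate(self) -> None:
        if self.n_amputees > self.n_subjects:
            raise ValueError("n_amputees cannot exceed n_subjects")
        if self.n_channels < self.ring_channels:
            raise ValueError("n_channels must be >= ring_channels")
        if min(self.gesture_duration_s, self.rest_duration_s) <= 0:
            raise ValueError("durations must be positive")
        if self.fs <= 0 or self.n_gestures < 1 or self.n_repetitions < 1:
            raise ValueError("fs, n_gestures, n_repetitions must be positive")


def _gesture_templates(cfg: SyntheticConfig) -> np.ndarray:
    """(n_gestures, n_channels) spatial activation patterns, cohort-level.

    Ring electrodes get a smooth von-Mises-like bump at a gesture-specific
    angle (plus a second harmonic for variety); extra electrodes get free
    positive weights.
    """
    rng = np.random.default_rng([cfg.seed, 0x7E41])
    G, C, R = cfg.n_gestures, cfg.n_channels, cfg.ring_channels
    t = np.zeros((G, C))
    angles = 2 * np.pi * np.arange(R) / R
    for g in range(G):
        mu = 2 * np.pi * g / G + rng.uniform(0, 2 * np.pi / G)
        kappa = rng.uniform(1.0, 3.0)
        bump = np.exp(kappa * (np.cos(angles - mu) - 1))
        harm = 0.3 * rng.uniform(0, 1) * (1 + np.cos(2 * (angles - mu))) / 2
        ring = 0.15 + bump + harm
        t[g, :R] = ring / ring.max()
        if C > R:
            t[g, R:] = rng.uniform(0.2, 1.0, size=C - R)
    return t


def _bandlimited_noise(rng, n, n_ch, fs, lo=20.0, hi=150.0) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to [lo, hi] Hz."""
    hi = min(hi, 0.45 * fs)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = rng.standard_normal((n, n_ch))
    y = scipy.signal.sosfiltfilt(sos, x, axis=0)
    return y / y.std(axis=0, keepdims=True)


def _envelope(n: int) -> np.ndarray:
    """Smooth on/off ramp (Tukey) over one gesture segment."""
    return scipy.signal.windows.tukey(n, alpha=0.3)


def simulate_subject(cfg: SyntheticConfig, subject_index: int) -> EmgRecording:
    """One subject's continuous recording with gesture/repetition labels.

    Schedule: for each gesture, ``n_repetitions`` executions separated by
    rest segments (rest also opens the recording and follows the last
    repetition of each gesture).
    """
    cfg.validate()
    amputee = subject_index >= cfg.n_subjects - cfg.n_amputees
    rng = np.random.default_rng([cfg.seed, 0x50B1, subject_index])
    templates = _gesture_templates(cfg)
    C, R = cfg.n_channels, cfg.ring_channels

    gain_sd = cfg.subject_gain_sd * (2.0 if amputee else 1.0)
    gains = np.exp(rng.normal(0.0, gain_sd, size=C))
    shift_max = cfg.electrode_shift_max * (2 if amputee else 1)
    shift = int(rng.integers(-shift_max, shift_max + 1)) if shift_max else 0
    atten = _AMPUTEE_ATTENUATION if amputee else 1.0

    subj_templates = templates.copy()
    if shift:
        subj_templates[:, :R] = np.roll(subj_templates[:, :R], shift, axis=1)

    n_g = int(round(cfg.gesture_duration_s * cfg.fs))
    n_r = int(round(cfg.rest_duration_s * cfg.fs))
    n_total = cfg.n_gestures * cfg.n_repetitions * (n_g + n_r) + n_r

    emg = np.zeros((n_total, C))
    stim = np.zeros(n_total, dtype=np.int64)
    rep = np.zeros(n_total, dtype=np.int64)

    env = _envelope(n_g)
    pos = n_r  # opening rest
    for g in range(cfg.n_gestures):
        for r in range(1, cfg.n_repetitions + 1):
            fatigue = max(0.2, 1.0 - _FATIGUE_SLOPE * (r - 1))
            carrier = _bandlimited_noise(rng, n_g, C, cfg.fs)
            seg = (carrier * env[:, None]
                   * subj_templates[g][None, :] * fatigue * atten)
            emg[pos:pos + n_g] = seg * _PEAK_UV
            stim[pos:pos + n_g] = g + 1
            rep[pos:pos + n_g] = r
            pos += n_g + n_r
    # subject gains, line hum and noise floor apply to the whole record
    emg *= gains[None, :]
    t = np.arange(n_total) / cfg.fs
    phases = rng.uniform(0, 2 * np.pi, size=C)
    emg += (cfg.line_interference_amp * _PEAK_UV
            * np.sin(2 * np.pi * 50.0 * t[:, None] + phases[None, :]))
    emg += cfg.noise_floor * _PEAK_UV * rng.standard_normal((n_total, C))

    rec = EmgRecording(
        emg=emg, fs=cfg.fs, stimulus=stim, repetition=rep,
        subject_id=f"S{subject_index:02d}", database_id="SYNTH",
        amputee=amputee,
        meta={"gains": gains, "shift": shift,
              "config": asdict(cfg)},
    )
    rec.validate()
    return rec


def simulate_cohort(cfg: SyntheticConfig) -> list[EmgRecording]:
    """All subjects of the cohort; the last ``n_amputees`` are flagged."""
    cfg.validate()
    return [simulate_subject(cfg, i) for i in range(cfg.n_subjects)]
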