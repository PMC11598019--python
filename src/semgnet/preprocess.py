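"""Filtering, rectification, normalization and overlapped windowing.

The pipeline order is fixed: band-pass + notch filter → optional
rectification → normalization → windowing. Normalization statistics are
always subject-specific and are fitted on training data only; three
methods are supported, each at two scopes (all channels pooled, or per
channel):

* ``range01``   — (x − min) / (max − min + ε), onto [0, 1]
* ``range_pm1`` — 2·(x − min) / (max − min + ε) − 1, onto [−1, 1]
* ``zscore``    — (x − mean) / (std + ε)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .io_emg import EmgRecording

__all__ = ["FilterSpec", "NormalizationStats", "WindowSet",
           "bandpass_notch", "rectify", "fit_normalization",
           "apply_normalization", "window_signal", "concat_window_sets",
           "NORM_METHODS", "NORM_SCOPES"]

NORM_METHODS = ("range01", "range_pm1", "zscore")
NORM_SCOPES = ("subject", "subject_channel")


@dataclass
class FilterSpec:
    """Fourth-order Butterworth band-pass (10–500 Hz) plus a 50 Hz notch."""

    band_low: float = 10.0
    band_high: float = 500.0
    order: int = 4
    notch_freq: float = 50.0
    notch_quality: float = 30.0

    def validate(self, fs: float) -> tuple[float, float]:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        hi = self.band_high
        nyq = fs / 2
        if hi >= nyq:
            hi = 0.95 * nyq
            warnings.warn(
                f"band_high={self.band_high} Hz >= Nyquist ({nyq} Hz); "
                f"clipping to {hi:.1f} Hz")
        if self.band_low >= hi:
            raise ValueError("pass band collapsed below Nyquist")
        return self.band_low, hi


@dataclass
class NormalizationStats:
    """Fitted per-subject statistics for one normalization method/scope.

    At ``subject`` scope the arrays are scalars (channels pooled); at
    ``subject_channel`` scope they are per-channel vectors.
    """

    method: str
    scope: str
    mean: np.ndarray
    std: np.ndarray
    min: np.ndarray
    max: np.ndarray
    subject_id: str = ""
    eps: float = 1e-8
    degenerate: bool = False   # zero-variance / zero-range data was guarded

    def validate(self, n_channels: int | None = None) -> None:
        if self.method not in NORM_METHODS:
            raise ValueError(f"unknown method {self.method!r}; "
                             f"expected one of {NORM_METHODS}")
        if self.scope not in NORM_SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if np.any(self.std < 0) or np.any(self.max < self.min):
            raise ValueError("invalid statistics (std < 0 or max < min)")
        if (self.scope == "subject_channel" and n_channels is not None
                and np.asarray(self.mean).shape != (n_channels,)):
            raise ValueError(
                f"per-channel stats of shape {np.asarray(self.mean).shape} do "
                f"not match channel count {n_channels}")


@dataclass
class WindowSet:
    """Segmented fixed-length windows: the model's training currency."""

    windows: np.ndarray          # (n_windows, window_len, n_channels)
    labels: np.ndarray           # class index per window (0..K-1)
    subject_ids: np.ndarray      # per window
    repetition_ids: np.ndarray   # per window
    window_len: int
    stride: int
    overlap_frac: float = 0.75
    fs: float = 0.0

    def __len__(self) -> int:
        return len(self.windows)

    def validate(self) -> None:
        n = len(self.windows)
        if not (len(self.labels) == len(self.subject_ids)
                == len(self.repetition_ids) == n):
            raise ValueError("per-window annotation lengths disagree")
        if n and self.windows.shape[1] != self.window_len:
            raise ValueError("window array second axis != window_len")
        expect = max(1, int(round(self.window_len * (1 - self.overlap_frac))))
        if self.stride != expect:
            raise ValueError(f"stride {self.stride} inconsistent with "
                             f"overlap_frac {self.overlap_frac} (expected {expect})")

    def subset(self, idx) -> "WindowSet":
        return replace(self, windows=self.windows[idx], labels=self.labels[idx],
                       subject_ids=self.subject_ids[idx],
                       repetition_ids=self.repetition_ids[idx])


def save_window_set(ws: WindowSet, path) -> None:
    import h5py
    ws.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ws.windows, track_times=False)
        f.create_dataset("labels", data=ws.labels, track_times=False)
        f.create_dataset("subject_ids",
                         data=np.asarray(ws.subject_ids, dtype="S"),
                         track_times=False)
        f.create_dataset("repetition_ids", data=ws.repetition_ids,
                         track_times=False)
        f.attrs.update({"window_len": ws.window_len, "stride": ws.stride,
                        "overlap_frac": ws.overlap_frac, "fs": ws.fs})


def load_window_set(path) -> WindowSet:
    import h5py
    with h5py.File(path, "r") as f:
        ws = WindowSet(
            windows=np.asarray(f["windows"]),
            labels=np.asarray(f["labels"]),
            subject_ids=np.array([s.decode() for s in f["subject_ids"]],
                                 dtype=object),
            repetition_ids=np.asarray(f["repetition_ids"]),
            window_len=int(f.attrs["window_len"]),
            stride=int(f.attrs["stride"]),
            overlap_frac=float(f.attrs["overlap_frac"]),
            fs=float(f.attrs["fs"]))
    ws.validate()
    return ws


def concat_window_sets(sets: list[WindowSet]) -> WindowSet:
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no non-empty window sets to concatenate")
    first = sets[0]
    return replace(first,
                   windows=np.concatenate([s.windows for s in sets]),
                   labels=np.concatenate([s.labels for s in sets]),
                   subject_ids=np.concatenate([s.subject_ids for s in sets]),
                   repetition_ids=np.concatenate([s.repetition_ids for s in sets]))


# ---------------------------------------------------------------------------
# filtering & rectification
# ---------------------------------------------------------------------------

def bandpass_notch(rec: EmgRecording, spec: FilterSpec | None = None,
                   zero_phase: bool = True) -> EmgRecording:
    """Band-pass + 50 Hz notch; zero-phase by default (offline processing),
    causal single-pass when ``zero_phase=False`` (real-time emulation)."""
    spec = spec or FilterSpec()
    lo, hi = spec.validate(rec.fs)
    sos = scipy.signal.butter(spec.order, [lo, hi], btype="bandpass",
                              fs=rec.fs, output="sos")
    b, a = scipy.signal.iirnotch(spec.notch_freq, spec.notch_quality, fs=rec.fs)
    if zero_phase:
        y = scipy.signal.sosfiltfilt(sos, rec.emg, axis=0)
        y = scipy.signal.filtfilt(b, a, y, axis=0)
    else:
        y = scipy.signal.sosfilt(sos, rec.emg, axis=0)
        y = scipy.signal.lfilter(b, a, y, axis=0)
    return replace(rec, emg=np.ascontiguousarray(y))


def rectify(rec: EmgRecording) -> EmgRecording:
    """Element-wise absolute value (classical EMG envelope precursor)."""
    return replace(rec, emg=np.abs(rec.emg))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _fit_samples(x: np.ndarray, method: str, scope: str, subject_id: str,
                 eps: float) -> NormalizationStats:
    axis = None if scope == "subject" else 0
    mean = np.asarray(x.mean(axis=axis))
    std = np.asarray(x.std(axis=axis))
    mn = np.asarray(x.min(axis=axis))
    mx = np.asarray(x.max(axis=axis))
    degenerate = bool(np.any(std == 0) or np.any(mx == mn))
    st = NormalizationStats(method=method, scope=scope, mean=mean, std=std,
                            min=mn, max=mx, subject_id=subject_id, eps=eps,
                            degenerate=degenerate)
    st.validate()
    return st


def fit_normalization(recs: list[EmgRecording], method: str, scope: str,
                      labelled_only: bool = True,
                      repetitions: set | None = None,
                      eps: float = 1e-8) -> dict[str, NormalizationStats]:
    """Fit per-subject statistics from (training) recordings.

    By default only gesture-labelled samples contribute; ``repetitions``
    additionally restricts to the given repetition ids, so stats can be
    computed from training repetitions alone.
    """
    if method not in NORM_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {NORM_METHODS}")
    if scope not in NORM_SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {NORM_SCOPES}")
    if not recs:
        raise ValueError("need at least one recording")
    by_subject: dict[str, list[np.ndarray]] = {}
    for rec in recs:
        mask = np.ones(rec.n_samples, dtype=bool)
        if labelled_only:
            mask &= rec.stimulus > 0
        if repetitions is not None:
            mask &= np.isin(rec.repetition, list(repetitions))
        if mask.any():
            by_subject.setdefault(rec.subject_id, []).append(rec.emg[mask])
    out = {}
    for sid, chunks in by_subject.items():
        x = np.concatenate(chunks, axis=0)
        out[sid] = _fit_samples(x, method, scope, sid, eps)
        if out[sid].degenerate:
            warnings.warn(f"subject {sid}: zero-variance/zero-range data; "
                          "eps guard active")
    return out


def apply_normalization(rec: EmgRecording, stats: NormalizationStats,
                        allow_subject_mismatch: bool = False) -> EmgRecording:
    """Normalize a recording with previously fitted statistics.

    ``allow_subject_mismatch`` covers the daily-recalibration scenario of
    applying one subject's statistics to another's data; by default a
    mismatch is an error.
    """
    stats.validate(rec.channel_count)
    if (stats.subject_id and rec.subject_id != stats.subject_id
            and not allow_subject_mismatch):
        raise ValueError(f"stats fitted on subject {stats.subject_id!r} "
                         f"applied to {rec.subject_id!r}")
    x = rec.emg
    if stats.method == "range01":
        y = (x - stats.min) / (stats.max - stats.min + stats.eps)
    elif stats.method == "range_pm1":
        y = 2.0 * (x - stats.min) / (stats.max - stats.min + stats.eps) - 1.0
    else:  # zscore
        y = (x - stats.mean) / (stats.std + stats.eps)
    return replace(rec, emg=y)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def _label_runs(stim: np.ndarray, rep: np.ndarray):
    """Maximal runs of constant non-rest (stimulus, repetition)."""
    n = len(stim)
    if n == 0:
        return
    change = np.flatnonzero((np.diff(stim) != 0) | (np.diff(rep) != 0))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [n]])
    for s, e in zip(starts, ends):
        if stim[s] > 0:
            yield s, e, int(stim[s]), int(rep[s])


def window_signal(rec: EmgRecording, window_ms: float,
                  overlap_frac: float = 0.75) -> WindowSet:
    """Cut fixed-length windows from label-pure gesture runs.

    A window never spans two gestures, two repetitions, or rest; each
    inherits its run's class (``stimulus − 1``) and repetition id. Stride
    is ``round(window_len · (1 − overlap))`` — one quarter window at the
    default 75 % overlap.
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    wl = int(round(window_ms * rec.fs / 1000.0))
    if wl < 1:
        raise ValueError(f"window of {window_ms} ms is shorter than one sample")
    stride = max(1, int(round(wl * (1.0 - overlap_frac))))
    wins, labels, reps = [], [], []
    for s, e, g, r in _label_runs(rec.stimulus, rec.repetition):
        for start in range(s, e - wl + 1, stride):
            wins.append(rec.emg[start:start + wl])
            labels.append(g - 1)
            reps.append(r)
    if not wins:
        warnings.warn(f"no run of subject {rec.subject_id} is at least "
                      f"{wl} samples long; empty window set")
        windows = np.empty((0, wl, rec.channel_count))
    else:
        windows = np.stack(wins)
    n = len(labels)
    ws = WindowSet(windows=windows,
                   labels=np.asarray(labels, dtype=np.int64),
                   subject_ids=np.full(n, rec.subject_id, dtype=object),
                   repetition_ids=np.asarray(reps, dtype=np.int64),
                   window_len=wl, stride=stride, overlap_frac=overlap_frac,
                   fs=rec.fs)
    ws.validate()
    return ws
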