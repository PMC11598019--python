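"""Reading NinaPro-style recordings and a self-describing HDF5 fixture format.

NinaPro DB2/DB3/DB7 distribute one MAT file per subject with an
``emg`` sample×channel matrix (2 kHz, Delsys electrodes), per-sample
gesture labels (``stimulus``, and the delay-corrected ``restimulus``) and
repetition indices (``repetition`` / ``rerepetition``). The reader prefers
the relabelled streams when present and records which was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import scipy.io

__all__ = ["EmgRecording", "read_ninapro_mat", "select_gestures",
           "write_fixture", "read_fixture"]


class FormatError(ValueError):
    """Input file does not follow the expected layout."""


@dataclass
class EmgRecording:
    """One subject's continuous multichannel sEMG with label streams.

    ``stimulus`` is 0 at rest and a positive gesture id otherwise;
    ``repetition`` is 0 at rest and the 1-based repetition index inside
    gesture segments. After harmonisation the two rest masks coincide.
    """

    emg: np.ndarray            # (n_samples, n_channels), ~±5000 μV scale
    fs: float
    stimulus: np.ndarray       # (n_samples,) int
    repetition: np.ndarray     # (n_samples,) int
    subject_id: str
    database_id: str = ""
    amputee: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def channel_count(self) -> int:
        return self.emg.shape[1]

    def validate(self) -> None:
        if self.emg.ndim != 2:
            raise FormatError("emg must be a 2-D sample×channel matrix")
        n = self.emg.shape[0]
        if len(self.stimulus) != n or len(self.repetition) != n:
            raise FormatError(
                f"label stream length mismatch: emg has {n} samples, "
                f"stimulus {len(self.stimulus)}, repetition {len(self.repetition)}")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")

    def harmonized(self) -> "EmgRecording":
        """Force repetition to 0 wherever stimulus is 0 (and vice versa)."""
        rest = self.stimulus == 0
        rep = np.where(rest, 0, self.repetition)
        stim = np.where(self.repetition == 0, 0, self.stimulus)
        stim = np.where(rest, 0, stim)
        return replace(self, stimulus=stim.astype(np.int64),
                       repetition=rep.astype(np.int64))


def _lower_keys(d) -> dict:
    return {str(k).lower(): k for k in d.keys()}


def _read_mat_fields(path) -> dict[str, np.ndarray]:
    try:
        raw = scipy.io.loadmat(path)
        return {str(k).lower(): np.asarray(v) for k, v in raw.items()
                if not k.startswith("__")}
    except (NotImplementedError, ValueError):
        # MAT v7.3 is an HDF5 container
        out = {}
        with h5py.File(path, "r") as f:
            for k in f.keys():
                v = f[k]
                if isinstance(v, h5py.Dataset):
                    out[str(k).lower()] = np.asarray(v).T  # v7.3 stores transposed
        return out


def _vec(a) -> np.ndarray:
    return np.asarray(a).reshape(-1).astype(np.int64)


def read_ninapro_mat(path, *, expected_channels: int | None = None,
                     fs: float = 2000.0) -> EmgRecording:
    """Read one subject's MAT file into an :class:`EmgRecording`.

    Prefers the delay-corrected ``restimulus``/``rerepetition`` streams over
    ``stimulus``/``repetition``; the choice is recorded under
    ``meta['label_source']``. Subjects recorded with fewer electrodes than
    ``expected_channels`` (as happens for one amputee) are zero-padded on
    the trailing channels with a validity mask in ``meta['channel_mask']``.
    """
    fields = _read_mat_fields(path)
    if "emg" not in fields:
        raise FormatError(f"{path}: no 'emg' matrix found")
    emg = np.asarray(fields["emg"], dtype=np.float64)
    if emg.ndim != 2:
        raise FormatError(f"{path}: emg must be 2-D, got shape {emg.shape}")

    if "restimulus" in fields:
        stim, label_source = _vec(fields["restimulus"]), "restimulus"
    elif "stimulus" in fields:
        stim, label_source = _vec(fields["stimulus"]), "stimulus"
    else:
        raise FormatError(f"{path}: no gesture-label vector "
                          "(stimulus/restimulus) found")
    if label_source == "restimulus" and "rerepetition" in fields:
        rep = _vec(fields["rerepetition"])
    elif "repetition" in fields:
        rep = _vec(fields["repetition"])
    elif "rerepetition" in fields:
        rep = _vec(fields["rerepetition"])
    else:
        rep = np.zeros_like(stim)
        warnings.warn(f"{path}: no repetition stream; filling with zeros")

    if len(stim) != emg.shape[0] or len(rep) != emg.shape[0]:
        raise FormatError(
            f"{path}: label stream length ({len(stim)}/{len(rep)}) does not "
            f"match emg sample count ({emg.shape[0]})")

    meta = {"label_source": label_source, "path": str(path)}
    if expected_channels is not None and emg.shape[1] < expected_channels:
        mask = np.zeros(expected_channels, dtype=bool)
        mask[:emg.shape[1]] = True
        emg = np.pad(emg, ((0, 0), (0, expected_channels - emg.shape[1])))
        meta["channel_mask"] = mask

    subject = fields.get("subject")
    subject_id = str(int(np.asarray(subject).reshape(-1)[0])) if subject is not None else ""

    rec = EmgRecording(emg=emg, fs=float(fs), stimulus=stim, repetition=rep,
                       subject_id=subject_id, meta=meta).harmonized()
    rec.validate()
    return rec


def select_gestures(rec: EmgRecording, gesture_ids) -> EmgRecording:
    """Keep rest plus the listed gestures, remapped to classes 0..K-1.

    Samples labelled with gestures outside the list are dropped; rest
    samples are retained (windowing decides their fate later). The
    id→class mapping, in list order, is stored in ``meta['gesture_map']``.
    """
    gesture_ids = list(gesture_ids)
    if not gesture_ids:
        raise ValueError("gesture_ids must be non-empty")
    if len(set(gesture_ids)) != len(gesture_ids):
        raise ValueError("gesture_ids must be unique")
    present = set(np.unique(rec.stimulus)) - {0}
    missing = [g for g in gesture_ids if g not in present]
    if missing:
        warnings.warn(f"gesture ids {missing} absent from recording "
                      f"{rec.subject_id}")
    remap = {g: i for i, g in enumerate(gesture_ids)}
    keep = (rec.stimulus == 0) | np.isin(rec.stimulus, gesture_ids)
    stim = rec.stimulus[keep]
    newstim = np.array([remap[s] + 1 if s else 0 for s in stim], dtype=np.int64)
    meta = dict(rec.meta)
    meta["gesture_map"] = remap
    out = replace(rec, emg=rec.emg[keep], stimulus=newstim,
                  repetition=rec.repetition[keep], meta=meta)
    return out.harmonized()


# ---------------------------------------------------------------------------
# fixture container
# ---------------------------------------------------------------------------

def write_fixture(rec: EmgRecording, path) -> None:
    """Save a recording as a self-describing HDF5 container.

    Timestamps are suppressed so identical recordings produce identical
    files byte for byte.
    """
    rec.validate()
    with h5py.File(path, "w", track_order=True) as f:
        for name, arr in (("emg", rec.emg), ("stimulus", rec.stimulus),
                          ("repetition", rec.repetition)):
            f.create_dataset(name, data=arr, track_times=False)
        f.attrs["fs"] = float(rec.fs)
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["database_id"] = rec.database_id
        f.attrs["amputee"] = bool(rec.amputee)
        f.attrs["channel_count"] = rec.channel_count
        if "label_source" in rec.meta:
            f.attrs["label_source"] = rec.meta["label_source"]


def read_fixture(path) -> EmgRecording:
    with h5py.File(path, "r") as f:
        meta = {}
        if "label_source" in f.attrs:
            meta["label_source"] = str(f.attrs["label_source"])
        rec = EmgRecording(
            emg=np.asarray(f["emg"]),
            fs=float(f.attrs["fs"]),
            stimulus=np.asarray(f["stimulus"]).astype(np.int64),
            repetition=np.asarray(f["repetition"]).astype(np.int64),
            subject_id=str(f.attrs["subject_id"]),
            database_id=str(f.attrs["database_id"]),
            amputee=bool(f.attrs["amputee"]),
            meta=meta,
        )
    rec.validate()
    return rec
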