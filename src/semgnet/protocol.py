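"""Data-splitting protocol: transfer-learning holdout and the inter-/
intra-subject pre-training splits.

Before any pre-training, a fixed group of subjects (canonically 12 healthy
+ 3 amputees) is set aside as the transfer-learning test pool and never
enters the pre-training partitions. The remaining subjects are split
either *inter-subject* (80 % of subjects train, 20 % validate — unseen
people measure generalisation) or *intra-subject* (per subject, repetitions
2, 4, 6 train / 1, 5 validate / 3 test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .preprocess import WindowSet

__all__ = ["SplitAssignment", "holdout_tl_subjects", "make_inter_subject_split",
           "make_intra_subject_split", "assign_windows",
           "INTRA_TRAIN_REPS", "INTRA_VAL_REPS", "INTRA_TEST_REPS"]

INTRA_TRAIN_REPS = frozenset({2, 4, 6})
INTRA_VAL_REPS = frozenset({1, 5})
INTRA_TEST_REPS = frozenset({3})


@dataclass
class SplitAssignment:
    """Membership bookkeeping for one pre-training split.

    ``mode="inter"`` partitions at the subject level (``train_subjects`` /
    ``val_subjects``); ``mode="intra"`` routes by repetition id within every
    subject (rep sets fixed to 2,4,6 / 1,5 / 3). ``holdout_subjects`` are
    excluded from all pre-training partitions.
    """

    mode: str
    train_subjects: list = field(default_factory=list)
    val_subjects: list = field(default_factory=list)
    holdout_subjects: list = field(default_factory=list)
    train_reps: frozenset = INTRA_TRAIN_REPS
    val_reps: frozenset = INTRA_VAL_REPS
    test_reps: frozenset = INTRA_TEST_REPS
    seed: int = 0

    def pretraining_subjects(self) -> set:
        return set(self.train_subjects) | set(self.val_subjects)

    def to_manifest(self) -> str:
        d = asdict(self)
        for k in ("train_reps", "val_reps", "test_reps"):
            d[k] = sorted(d[k])
        return json.dumps(d, indent=2, default=str)


def holdout_tl_subjects(subjects, amputee_flags, n_healthy: int,
                        n_amputee: int, seed: int = 0):
    """Draw the transfer-learning holdout: ``n_healthy`` + ``n_amputee``
    subjects, deterministically given the seed. Returns (holdout, remainder)
    in stable subject order."""
    subjects = list(subjects)
    flags = list(amputee_flags)
    if len(subjects) != len(flags):
        raise ValueError("subjects and amputee_flags lengths differ")
    healthy = [s for s, a in zip(subjects, flags) if not a]
    amputees = [s for s, a in zip(subjects, flags) if a]
    if n_healthy > len(healthy):
        raise ValueError(f"requested {n_healthy} healthy holdout subjects, "
                         f"only {len(healthy)} available")
    if n_amputee > len(amputees):
        raise ValueError(f"requested {n_amputee} amputee holdout subjects, "
                         f"only {len(amputees)} available")
    rng = np.random.default_rng([seed, 0x401D])
    chosen = set(rng.choice(len(healthy), size=n_healthy, replace=False).tolist()
                 ) if n_healthy else set()
    chosen_a = set(rng.choice(len(amputees), size=n_amputee, replace=False).tolist()
                   ) if n_amputee else set()
    hold = ({healthy[i] for i in chosen} | {amputees[i] for i in chosen_a})
    holdout = [s for s in subjects if s in hold]
    remainder = [s for s in subjects if s not in hold]
    return holdout, remainder


def make_inter_subject_split(remainder, train_frac: float = 0.8,
                             seed: int = 0,
                             holdout_subjects=()) -> SplitAssignment:
    """Subject-level train/validation partition at ``train_frac``.

    The validation side is floored, the remainder goes to training (keeps
    maximum variability on the training side).
    """
    remainder = list(remainder)
    if len(remainder) < 2:
        raise ValueError("need at least 2 subjects for an inter-subject split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n_val = int(np.floor(np.round(len(remainder) * (1 - train_frac), 9)))
    n_val = max(1, n_val)
    if n_val >= len(remainder):
        raise ValueError("degenerate partition: no training subjects left")
    rng = np.random.default_rng([seed, 0x1217])
    perm = rng.permutation(len(remainder))
    val = sorted(remainder[i] for i in perm[:n_val])
    train = sorted(remainder[i] for i in perm[n_val:])
    return SplitAssignment(mode="inter", train_subjects=train,
                           val_subjects=val,
                           holdout_subjects=list(holdout_subjects), seed=seed)


def make_intra_subject_split(remainder, available_reps=None,
                             holdout_subjects=(), seed: int = 0) -> SplitAssignment:
    """Repetition-routed split within every subject (2,4,6 / 1,5 / 3)."""
    remainder = list(remainder)
    if not remainder:
        raise ValueError("no subjects to split")
    required = INTRA_TRAIN_REPS | INTRA_VAL_REPS | INTRA_TEST_REPS
    if available_reps is not None:
        missing = sorted(required - set(available_reps))
        if missing:
            raise ValueError(f"recordings lack repetitions {missing}")
    return SplitAssignment(mode="intra", train_subjects=sorted(remainder),
                           val_subjects=sorted(remainder),
                           holdout_subjects=list(holdout_subjects), seed=seed)


def assign_windows(ws: WindowSet, split: SplitAssignment):
    """Index arrays (train, val, test) routing every window of the
    pre-training pool; holdout-subject windows are rejected outright."""
    sids = np.asarray(ws.subject_ids)
    if split.holdout_subjects:
        leaked = np.isin(sids, list(split.holdout_subjects))
        if leaked.any():
            bad = sorted(set(sids[leaked]))
            raise ValueError(f"holdout subjects {bad} present in the "
                             "pre-training window pool")
    if split.mode == "inter":
        train = np.flatnonzero(np.isin(sids, split.train_subjects))
        val = np.flatnonzero(np.isin(sids, split.val_subjects))
        test = np.array([], dtype=np.int64)
    elif split.mode == "intra":
        member = np.isin(sids, split.train_subjects)
        reps = ws.repetition_ids
        present = set(np.unique(reps[member]).tolist())
        missing = sorted((INTRA_TRAIN_REPS | INTRA_VAL_REPS | INTRA_TEST_REPS)
                         - present)
        if missing:
            raise ValueError(f"window pool lacks repetitions {missing}")
        train = np.flatnonzero(member & np.isin(reps, list(split.train_reps)))
        val = np.flatnonzero(member & np.isin(reps, list(split.val_reps)))
        test = np.flatnonzero(member & np.isin(reps, list(split.test_reps)))
    else:
        raise ValueError(f"unknown split mode {split.mode!r}")
    return train, val, test
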