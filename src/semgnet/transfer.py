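"""Subject-specific fine-tuning of a pre-trained backbone.

Two regimes, differing in how much of the network adapts to the new user:

* ``last``   — only Part 4 (the two final linear layers) is retrained;
* ``middle`` — Parts 3 and 4 are retrained, Parts 1–2 stay frozen.

For each held-out subject a repetition-level 5-fold cross-validation is
run: every fold retrains on ``n_repetitions_for_retraining`` repetitions,
early-stops on a disjoint validation repetition and is scored on a
disjoint test repetition. ``n_repetitions_for_retraining = 0`` degenerates
to zero-shot evaluation of the pre-trained model.

Because the frozen prefix is deterministic in eval mode, its activations
are computed once per subject and cached; only the trainable suffix is
iterated during fine-tuning. Fine-tuning continues from the pre-trained
weights (it does not re-initialise the retrained layers).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Adam, SGD, Context, DTYPE
from .metrics import MetricsReport, compute_metrics, mean_std_table
from .model import MscnnModel, _state_arrays
from .preprocess import WindowSet

__all__ = ["TLConfig", "TLResult", "CohortTLResult", "freeze_for_mode",
           "repetition_folds", "finetune_subject", "evaluate_cohort"]

MODES = {"last": ("part4",), "middle": ("part3", "part4")}


@dataclass
class TLConfig:
    mode: str = "last"
    n_repetitions_for_retraining: int = 4
    n_folds: int = 5
    max_epochs: int = 30
    patience: int = 8
    learning_rate: float = 5e-4   # reduced w.r.t. pre-training
    batch_size: int = 64
    optimizer: str = "adam"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown transfer mode {self.mode!r}; "
                             f"expected one of {tuple(MODES)}")
        if not 0 <= self.n_repetitions_for_retraining <= 4:
            raise ValueError("n_repetitions_for_retraining must be in 0..4")


@dataclass
class TLResult:
    """Per-subject fine-tuning outcome over repetition folds."""

    subject_id: str
    mode: str
    folds: list = field(default_factory=list)   # per-fold dicts
    zero_shot: MetricsReport | None = None      # all repetitions, no tuning
    zero_shot_fold_mean: float = float("nan")   # zero-shot on fold test reps

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f["accuracy"] for f in self.folds])

    @property
    def fold_f1s(self) -> np.ndarray:
        return np.array([f["f1"] for f in self.folds])

    @property
    def accuracy(self) -> float:
        return float(self.fold_accuracies.mean()) if self.folds else \
            float(self.zero_shot.accuracy)

    @property
    def f1(self) -> float:
        return float(self.fold_f1s.mean()) if self.folds else \
            float(self.zero_shot.f1)

    @property
    def best_epoch(self) -> float:
        return float(np.mean([f["best_epoch"] for f in self.folds])) \
            if self.folds else float("nan")


@dataclass
class CohortTLResult:
    per_subject: dict[str, TLResult]
    amputee: dict[str, bool] = field(default_factory=dict)

    def aggregate(self, metric: str = "accuracy", subset: str = "all"):
        """(mean, std) across subjects; subset in {all, healthy, amputee}."""
        vals = [getattr(r, metric) for sid, r in self.per_subject.items()
                if subset == "all"
                or (subset == "healthy" and not self.amputee.get(sid))
                or (subset == "amputee" and self.amputee.get(sid))]
        if not vals:
            return float("nan"), float("nan")
        return float(np.mean(vals)), float(np.std(vals))

    def table(self) -> str:
        rows = {sid: {"accuracy": r.accuracy, "f1": r.f1}
                for sid, r in self.per_subject.items()}
        return mean_std_table(rows)


# ---------------------------------------------------------------------------
# freezing & folds
# ---------------------------------------------------------------------------

def freeze_for_mode(model: MscnnModel, mode: str) -> MscnnModel:
    """Set the trainable flags of the given transfer regime (in place)."""
    if mode not in MODES:
        raise ValueError(f"unknown transfer mode {mode!r}")
    flags = {p: p in MODES[mode] for p in ("part1", "part2", "part3", "part4")}
    if model.domain_head is not None:
        flags["domain"] = False
    model.set_trainable(flags)
    return model


def repetition_folds(available_reps, k: int, n_folds: int = 5,
                     seed: int = 0):
    """Sample ``n_folds`` distinct (retrain_reps, val_rep, test_rep)
    assignments with pairwise-disjoint roles, without replacement from all
    valid combinations."""
    reps = sorted(set(int(r) for r in available_reps))
    if k < 1:
        raise ValueError("need at least one retraining repetition")
    if k > len(reps) - 2:
        raise ValueError(
            f"k={k} retraining repetitions leave no disjoint validation and "
            f"test repetition among {reps}")
    combos = []
    for retrain in itertools.combinations(reps, k):
        rest = [r for r in reps if r not in retrain]
        for val, test in itertools.permutations(rest, 2):
            combos.append((tuple(retrain), val, test))
    if n_folds > len(combos):
        raise ValueError(f"only {len(combos)} valid fold assignments exist, "
                         f"{n_folds} requested")
    rng = np.random.default_rng([seed, 0xF01D])
    pick = rng.choice(len(combos), size=n_folds, replace=False)
    return [combos[i] for i in sorted(pick)]


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def _prefix_features(model: MscnnModel, X: np.ndarray, mode: str,
                     batch_size: int = 256) -> np.ndarray:
    """Eval-mode activations of the frozen prefix (cache point)."""
    ctx = Context(training=False)
    fn = model.features if mode == "last" else model.part2_output
    return np.concatenate(
        [fn(X[i:i + batch_size], ctx).data for i in range(0, len(X), batch_size)],
        axis=0)


def _suffix_logits(model: MscnnModel, feats, ctx: Context) -> Tensor:
    t = feats if isinstance(feats, Tensor) else Tensor(np.asarray(feats, DTYPE))
    if t.data.ndim == 2:      # flatten-level cache: Part 4 only
        return model.part4(t, ctx)
    return model.part4(model.part3(t, ctx), ctx)


def _suffix_predict(model: MscnnModel, feats: np.ndarray,
                    batch_size: int = 512) -> np.ndarray:
    ctx = Context(training=False)
    out = [_suffix_logits(model, feats[i:i + batch_size], ctx).data.argmax(1)
           for i in range(0, len(feats), batch_size)]
    return np.concatenate(out)


def finetune_subject(pretrained: MscnnModel, subject_windows: WindowSet,
                     tl: TLConfig, pretraining_subjects=()) -> TLResult:
    """Repetition-fold cross-validated fine-tuning for one unseen subject.

    The pre-trained model is cloned per fold; the original is never
    modified. Raises if the subject took part in pre-training.
    """
    tl.validate()
    sids = set(np.asarray(subject_windows.subject_ids).tolist())
    if len(sids) != 1:
        raise ValueError(f"expected windows of exactly one subject, got {sids}")
    sid = next(iter(sids))
    if sid in set(pretraining_subjects):
        raise ValueError(f"subject {sid!r} leaked from the pre-training pool")

    X = np.asarray(subject_windows.windows, dtype=DTYPE)
    y = np.asarray(subject_windows.labels)
    reps = np.asarray(subject_windows.repetition_ids)
    n_classes = pretrained.cfg.n_classes

    zero_preds = pretrained.predict(X)
    result = TLResult(subject_id=sid, mode=tl.mode,
                      zero_shot=compute_metrics(zero_preds, y, n_classes))
    if tl.n_repetitions_for_retraining == 0:
        return result

    folds = repetition_folds(np.unique(reps), tl.n_repetitions_for_retraining,
                             tl.n_folds, seed=tl.seed)
    feats = _prefix_features(pretrained, X, tl.mode)
    zs_fold = []
    for fold_i, (retrain, val_rep, test_rep) in enumerate(folds):
        tr = np.flatnonzero(np.isin(reps, retrain))
        va = np.flatnonzero(reps == val_rep)
        te = np.flatnonzero(reps == test_rep)
        if not (len(tr) and len(va) and len(te)):
            raise ValueError(f"fold {fold_i}: empty partition for "
                             f"({retrain}, {val_rep}, {test_rep})")
        model = freeze_for_mode(pretrained.clone(), tl.mode)
        best_epoch = _train_suffix(model, feats, y, tr, va, tl, fold_i)
        preds = _suffix_predict(model, feats[te])
        rep_metrics = compute_metrics(preds, y[te], n_classes,
                                      best_epoch=best_epoch)
        zs_fold.append(float((zero_preds[te] == y[te]).mean()))
        result.folds.append({
            "retrain_reps": retrain, "val_rep": val_rep, "test_rep": test_rep,
            "accuracy": rep_metrics.accuracy, "f1": rep_metrics.f1,
            "best_epoch": best_epoch,
        })
    result.zero_shot_fold_mean = float(np.mean(zs_fold))
    return result


def _train_suffix(model: MscnnModel, feats: np.ndarray, y: np.ndarray,
                  tr: np.ndarray, va: np.ndarray, tl: TLConfig,
                  fold_i: int) -> int:
    params = model.parameters(trainable_only=True)
    if tl.optimizer.lower() == "sgd":
        opt = SGD(params, lr=tl.learning_rate)
    else:
        opt = Adam(params, lr=tl.learning_rate)
    rng = np.random.default_rng([tl.seed, 0x7F, fold_i])
    ctx = Context(training=True, rng=rng)
    best_val, best_state, best_epoch, bad = np.inf, None, 0, 0
    for epoch in range(tl.max_epochs):
        order = rng.permutation(len(tr))
        for s in range(0, len(order), tl.batch_size):
            b = tr[order[s:s + tl.batch_size]]
            if len(b) < 2:
                continue
            opt.zero_grad()
            logits = _suffix_logits(model, feats[b], ctx)
            loss = ad.softmax_cross_entropy(logits, y[b])
            loss.backward()
            opt.step()
        # validation loss, eval mode
        vctx = Context(training=False)
        vlogits = _suffix_logits(model, feats[va], vctx)
        vl = float(ad.softmax_cross_entropy(vlogits.detach(), y[va]).item())
        if vl < best_val - 1e-6:
            best_val, best_epoch, bad = vl, epoch, 0
            best_state = {k: v.copy() for k, v in _state_arrays(model).items()}
        else:
            bad += 1
            if bad >= tl.patience:
                break
    if best_state is not None:
        for k, arr in _state_arrays(model).items():
            arr[...] = best_state[k]
    return best_epoch


def evaluate_cohort(pretrained: MscnnModel, holdout: list[WindowSet],
                    tl: TLConfig, pretraining_subjects=(),
                    amputee: dict[str, bool] | None = None) -> CohortTLResult:
    """Fine-tune and score every held-out subject; aggregate mean ± std.

    A non-empty intersection between holdout and pre-training subjects is a
    hard error (leakage guard).
    """
    if not holdout:
        raise ValueError("empty holdout")
    hold_ids = [str(np.asarray(ws.subject_ids)[0]) for ws in holdout]
    leak = set(hold_ids) & set(pretraining_subjects)
    if leak:
        raise ValueError(f"holdout subjects {sorted(leak)} appear in the "
                         "pre-training pool")
    per = {}
    for ws in holdout:
        res = finetune_subject(pretrained, ws, tl, pretraining_subjects)
        per[res.subject_id] = res
    return CohortTLResult(per_subject=per, amputee=dict(amputee or {}))
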