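"""Backbone pre-training: standard, triplet-margin and domain-adversarial.

Three strategies produce the backbone that transfer learning later adapts:

* ``standard`` — plain softmax cross-entropy on the gesture classes.
* ``triplet`` — metric learning on the Part-3 flatten embeddings with the
  hinge loss ``Σ max(0, margin + d(a,p) − d(a,n))``; a *positive* shares the
  anchor's gesture but comes from a **different subject**, a *negative* is
  any window with a different gesture. No gradients flow through the class
  head.
* ``dann`` — a subject-classification head identical to Part 4 is attached
  behind a gradient-reversal operator, so the backbone is pushed to make
  subject identity unpredictable while staying discriminative for gestures:
  ``min L_c − λ·L_d``. λ follows the sigmoidal schedule
  ``λ(p) = 2/(1+exp(−γ·p)) − 1`` over training progress p.

Early stopping monitors validation loss and restores the best weights.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import Adam, SGD, Context, DTYPE
from .model import MscnnModel, _state_arrays
from .preprocess import WindowSet
from .protocol import SplitAssignment, assign_windows

__all__ = ["TrainConfig", "TripletBatch", "TrainHistory",
           "triplet_margin_loss", "sample_triplets", "dann_lambda",
           "train_backbone", "grid_search", "evaluate_windows"]

STRATEGIES = ("standard", "triplet", "dann")


@dataclass
class TrainConfig:
    strategy: str = "standard"
    batch_size: int = 256
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    max_epochs: int = 50
    patience: int = 10
    margin: float = 1.0        # triplet hinge margin
    lambda_gamma: float = 10.0  # steepness of the DANN λ schedule
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; "
                             f"expected one of {STRATEGIES}")
        if self.strategy in ("triplet", "dann") and self.batch_size < 2:
            raise ValueError("triplet/dann need batch_size >= 2")
        if self.patience > self.max_epochs and self.max_epochs > 0:
            raise ValueError("patience cannot exceed max_epochs")
        if self.optimizer.lower() not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TripletBatch:
    """Anchor/positive/negative embedding triples with their metadata."""

    anchor: object      # Tensor or ndarray (B, D)
    positive: object
    negative: object
    subjects: np.ndarray = None   # (B, 3) subject per role
    labels: np.ndarray = None     # (B, 3) gesture label per role
    indices: np.ndarray = None    # (B, 3) row indices into the pool


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    class_loss: list = field(default_factory=list)    # L_c per epoch (dann)
    domain_loss: list = field(default_factory=list)   # L_d per epoch (dann)
    lambdas: list = field(default_factory=list)       # λ_t per epoch (dann)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# losses and schedules
# ---------------------------------------------------------------------------

def _pairwise_dist(a, b) -> Tensor:
    diff = ad.sub(a, b)
    return ad.sqrt(ad.tsum(ad.mul(diff, diff), axis=1), eps=1e-12)


def triplet_margin_loss(batch: TripletBatch, margin: float):
    """Σ_i max(0, margin + d(aᵢ,pᵢ) − d(aᵢ,nᵢ)) with Euclidean d."""
    a = batch.anchor if isinstance(batch.anchor, Tensor) else Tensor(np.asarray(batch.anchor))
    p = batch.positive if isinstance(batch.positive, Tensor) else Tensor(np.asarray(batch.positive))
    n = batch.negative if isinstance(batch.negative, Tensor) else Tensor(np.asarray(batch.negative))
    if not (a.shape == p.shape == n.shape):
        raise ValueError("anchor/positive/negative embedding shapes differ")
    hinge = ad.leaky_relu(
        ad.add(ad.sub(_pairwise_dist(a, p), _pairwise_dist(a, n)), float(margin)),
        0.0)
    return ad.tsum(hinge)


def sample_triplets(pool, embeddings, rng: np.random.Generator,
                    labels=None, n_triplets: int | None = None) -> TripletBatch:
    """Uniformly sample valid (anchor, positive, negative) index triples.

    ``pool`` is either a :class:`WindowSet` (whose subject/label annotations
    are used) or an array of subject ids with ``labels`` given separately.
    Positives share the anchor's label but come from a different subject;
    negatives have a different label. Anchors with no valid positive are
    skipped; a pool with a single subject (no positives at all) is an error.
    """
    if isinstance(pool, WindowSet):
        subjects, labels = pool.subject_ids, pool.labels
    else:
        subjects = pool
        if labels is None:
            raise ValueError("labels required when pool is not a WindowSet")
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    n = len(labels)
    if len(np.unique(subjects)) < 2:
        raise ValueError("triplet sampling needs at least two subjects in "
                         "the pool (positives are cross-subject)")
    if len(np.unique(labels)) < 2:
        raise ValueError("triplet sampling needs at least two classes")
    anchors = np.arange(n) if n_triplets is None else \
        rng.integers(0, n, size=n_triplets)
    ai, pi, ni = [], [], []
    for i in anchors:
        pos_mask = (labels == labels[i]) & (subjects != subjects[i])
        neg_mask = labels != labels[i]
        if not pos_mask.any() or not neg_mask.any():
            continue
        pos_idx = np.flatnonzero(pos_mask)
        neg_idx = np.flatnonzero(neg_mask)
        ai.append(i)
        pi.append(pos_idx[rng.integers(0, len(pos_idx))])
        ni.append(neg_idx[rng.integers(0, len(neg_idx))])
    if not ai:
        raise ValueError("no valid triplets in the pool")
    ai, pi, ni = np.asarray(ai), np.asarray(pi), np.asarray(ni)

    def take(e, idx):
        if isinstance(e, Tensor):
            return _rows(e, idx)
        return np.asarray(e)[idx]

    return TripletBatch(
        anchor=take(embeddings, ai), positive=take(embeddings, pi),
        negative=take(embeddings, ni),
        subjects=np.stack([subjects[ai], subjects[pi], subjects[ni]], axis=1),
        labels=np.stack([labels[ai], labels[pi], labels[ni]], axis=1),
        indices=np.stack([ai, pi, ni], axis=1))


def _rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Differentiable row gather."""
    out_data = t.data[idx]

    def bwd(g):
        d = np.zeros_like(t.data)
        np.add.at(d, idx, g)
        ad._accum(t, d)

    return ad._make(out_data, (t,), bwd, t.requires_grad)


def dann_lambda(progress: float, gamma: float = 10.0) -> float:
    """Sigmoidal ramp of the gradient-reversal strength over training
    progress p ∈ [0,1]: λ(p) = 2/(1+e^{−γp}) − 1, rising from 0 toward 1."""
    if not 0.0 <= progress <= 1.0:
        raise ValueError("progress must lie in [0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(2.0 / (1.0 + np.exp(-gamma * progress)) - 1.0)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def evaluate_windows(model: MscnnModel, windows, labels,
                     batch_size: int = 512):
    """Eval-mode mean cross-entropy and accuracy."""
    ctx = Context(training=False)
    losses, correct = [], 0
    labels = np.asarray(labels)
    for i in range(0, len(windows), batch_size):
        xb = windows[i:i + batch_size]
        yb = labels[i:i + batch_size]
        logits = model.forward(xb, ctx)
        losses.append(float(ad.softmax_cross_entropy(
            logits.detach(), yb).item()) * len(yb))
        correct += int((logits.data.argmax(axis=1) == yb).sum())
    n = len(labels)
    return sum(losses) / n, correct / n


def _domain_indexer(subject_ids) -> dict:
    return {s: i for i, s in enumerate(sorted(set(subject_ids)))}


def train_backbone(model: MscnnModel, splits: SplitAssignment,
                   data: WindowSet, cfg: TrainConfig,
                   verbose: bool = False):
    """Pre-train the backbone on the split's train/val partitions.

    Returns ``(model, TrainHistory)``; the model is trained in place and
    ends with the best-validation weights restored.
    """
    cfg.validate()
    tr_idx, va_idx, _ = assign_windows(data, splits)
    if len(tr_idx) == 0 or len(va_idx) == 0:
        raise ValueError("train/validation partitions must be non-empty")
    X = np.asarray(data.windows, dtype=DTYPE)
    y = np.asarray(data.labels)
    subjects = np.asarray(data.subject_ids)

    if cfg.strategy == "dann":
        dom_map = _domain_indexer(subjects[np.concatenate([tr_idx, va_idx])])
        dom = np.array([dom_map[s] for s in subjects])
        if model.domain_head is None:
            model.add_domain_head(len(dom_map))
        elif model.domain_head.layers[2].bias.size != len(dom_map):
            raise ValueError("domain head width does not match the number of "
                             "pre-training subjects")
    if cfg.strategy == "triplet" and len(set(subjects[tr_idx])) < 2:
        raise ValueError("triplet pre-training needs >= 2 training subjects")

    rng = np.random.default_rng([cfg.seed, 0x7124])
    trip_rng = np.random.default_rng([cfg.seed, 0x7125])
    ctx = Context(training=True, rng=rng)

    if cfg.strategy == "triplet":
        parts = ["part1", "part2", "part3"]
    elif cfg.strategy == "dann":
        parts = ["part1", "part2", "part3", "part4", "domain"]
    else:
        parts = ["part1", "part2", "part3", "part4"]
    params = model.parameters(parts=parts, trainable_only=True)
    if cfg.optimizer.lower() == "sgd":
        opt = SGD(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    else:
        opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    # fixed validation triplet indices so the early-stopping metric is
    # comparable across epochs
    if cfg.strategy == "triplet":
        val_trip = sample_triplets(subjects[va_idx],
                                   np.zeros((len(va_idx), 1)),
                                   np.random.default_rng([cfg.seed, 0x7126]),
                                   labels=y[va_idx],
                                   n_triplets=min(512, 4 * len(va_idx)))

    hist = TrainHistory()
    best_val = np.inf
    best_state = None
    bad_epochs = 0

    for epoch in range(cfg.max_epochs):
        progress = epoch / max(1, cfg.max_epochs - 1)
        lam = dann_lambda(progress, cfg.lambda_gamma) if cfg.strategy == "dann" else None
        order = rng.permutation(len(tr_idx))
        ep_loss = ep_lc = ep_ld = 0.0
        ep_n = ep_correct = 0
        for start in range(0, len(order), cfg.batch_size):
            b = tr_idx[order[start:start + cfg.batch_size]]
            if len(b) < 2:
                continue
            xb, yb = X[b], y[b]
            opt.zero_grad()
            if cfg.strategy == "standard":
                logits = model.forward(xb, ctx)
                loss = ad.softmax_cross_entropy(logits, yb)
                ep_correct += int((logits.data.argmax(1) == yb).sum())
            elif cfg.strategy == "dann":
                logits, dlogits = model.forward(xb, ctx, domain_lambda=lam)
                lc = ad.softmax_cross_entropy(logits, yb)
                ld = ad.softmax_cross_entropy(dlogits, dom[b])
                loss = ad.add(lc, ld)
                ep_lc += lc.item() * len(b)
                ep_ld += ld.item() * len(b)
                ep_correct += int((logits.data.argmax(1) == yb).sum())
            else:  # triplet
                emb = model.features(xb, ctx)
                try:
                    tb = sample_triplets(subjects[b], emb, trip_rng, labels=yb)
                except ValueError:
                    continue
                loss = ad.scale(triplet_margin_loss(tb, cfg.margin),
                                1.0 / len(tb.indices))
            loss.backward()
            opt.step()
            ep_loss += loss.item() * len(b)
            ep_n += len(b)

        hist.train_loss.append(ep_loss / max(1, ep_n))
        hist.train_acc.append(ep_correct / max(1, ep_n))
        if cfg.strategy == "dann":
            hist.class_loss.append(ep_lc / max(1, ep_n))
            hist.domain_loss.append(ep_ld / max(1, ep_n))
            hist.lambdas.append(lam)

        # validation
        if cfg.strategy == "triplet":
            emb = _eval_features(model, X[va_idx])
            tb = TripletBatch(anchor=emb[val_trip.indices[:, 0]],
                              positive=emb[val_trip.indices[:, 1]],
                              negative=emb[val_trip.indices[:, 2]])
            vl = float(triplet_margin_loss(tb, cfg.margin).item()) / len(val_trip.indices)
            va = float("nan")
        else:
            vl, va = evaluate_windows(model, X[va_idx], y[va_idx])
        hist.val_loss.append(vl)
        hist.val_acc.append(va)
        if verbose:
            print(f"epoch {epoch}: train {hist.train_loss[-1]:.4f} "
                  f"val {vl:.4f} acc {va:.3f}")

        if vl < best_val - 1e-6:
            best_val = vl
            hist.best_epoch = epoch
            best_state = {k: v.copy() for k, v in _state_arrays(model).items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break

    if best_state is not None:
        for k, arr in _state_arrays(model).items():
            arr[...] = best_state[k]
    return model, hist


def _eval_features(model: MscnnModel, X: np.ndarray,
                   batch_size: int = 512) -> np.ndarray:
    ctx = Context(training=False)
    out = [model.features(X[i:i + batch_size], ctx).data
           for i in range(0, len(X), batch_size)]
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# hyperparameter grid harness
# ---------------------------------------------------------------------------

def grid_search(space: dict, train_fn, budget: int | None = None,
                seed: int = 0):
    """Evaluate configurations from the cartesian grid ``space``.

    ``train_fn(config) -> float`` returns a validation metric (higher is
    better). With a ``budget`` the grid is subsampled deterministically.
    Returns the configurations ranked best-first as
    ``[(config, metric), ...]``.
    """
    if not space:
        raise ValueError("empty search space")
    keys = list(space.keys())
    combos = [dict(zip(keys, vals))
              for vals in itertools.product(*(space[k] for k in keys))]
    if budget is not None and budget < len(combos):
        rng = np.random.default_rng([seed, 0x621D])
        pick = rng.choice(len(combos), size=budget, replace=False)
        combos = [combos[i] for i in sorted(pick)]
    results = [(c, float(train_fn(c))) for c in combos]
    return sorted(results, key=lambda r: -r[1])
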