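"""The four-part multi-scale CNN for windowed sEMG classification.

The network consumes raw sEMG windows shaped ``(n_windows, window_len,
n_channels)`` as single-channel images and is organised in four addressable
parts:

* **Part 1** — five parallel branches. Each branch opens with a 2-D
  convolution whose temporal kernel extent grows linearly across branches
  (``i·W × 3`` with ``W = window_len // 20``), so the bank covers several
  temporal scales at once. The first eight electrodes sit on a ring around
  the forearm, so the opening convolution pads the electrode axis
  circularly over that ring (zero beyond it) and the time axis with zeros.
  A separable convolution block with twice the channel width follows.
* **Part 2** — channel concatenation of the five branches and a 1×1
  convolution that fuses them down to ``post_concat_channels`` maps.
* **Part 3** — two separable-convolution stages ending in a flatten; its
  output is the embedding used for metric pre-training and as the input of
  the classification head.
* **Part 4** — two linear layers producing class scores. A *domain head*
  with the same shape (sized to the number of training subjects) can be
  attached behind a gradient-reversal operator for domain-adversarial
  pre-training.

Each part carries a trainable flag so transfer-learning regimes can freeze
prefixes of the network (see :mod:`semgnet.transfer`).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gradient_reversal
from .layers import (Activation, Adam, BatchNorm2d, Context, Conv2d, Dropout2d,
                     DTYPE, Flatten, Linear, MaxPool2d, Module,
                     SeparableConv2d, Sequential)

__all__ = ["ModelConfig", "MscnnModel", "build_mscnn", "circular8_pad",
           "infer_shapes", "count_trainable", "gradient_reversal",
           "save_checkpoint", "load_checkpoint"]

PART_NAMES = ("part1", "part2", "part3", "part4")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``base_kernel`` (the temporal kernel increment W) is derived as
    ``window_len // 20``; branch *i* (1-based) uses a kernel of
    ``i * W × 3``.
    """

    window_len: int = 300
    n_channels: int = 12
    n_classes: int = 14
    n_branches: int = 5
    block1_channels: int = 32
    post_concat_channels: int = 128
    sepconv_channels: int = 256
    activation: str = "leaky_relu"
    dropout_rate: float = 0.2
    temporal_pool: int = 15
    ring_channels: int = 8
    pad_electrodes: int = 2
    seed: int = 0

    @property
    def base_kernel(self) -> int:
        return max(1, self.window_len // 20)

    @property
    def kernel_sizes(self) -> list[int]:
        return [self.base_kernel * i for i in range(1, self.n_branches + 1)]

    @property
    def concat_channels(self) -> int:
        return self.n_branches * 2 * self.block1_channels

    def spatial_trace(self) -> list[tuple[int, int]]:
        """(time, electrode) extent after each resolution-changing stage."""
        t, e = self.window_len, self.n_channels + self.pad_electrodes
        out = [(t, e)]
        t //= self.temporal_pool
        out.append((t, e))
        t, e = t // 2, e // 2
        out.append((t, e))
        t, e = t // 2, e // 2
        out.append((t, e))
        t, e = t // 2, e // 2
        out.append((t, e))
        return out

    @property
    def flatten_width(self) -> int:
        t, e = self.spatial_trace()[-1]
        return self.sepconv_channels * t * e

    def validate(self) -> None:
        if self.window_len < 20:
            raise ValueError("window_len must be >= 20 so the kernel increment is >= 1")
        if self.n_channels < self.ring_channels:
            raise ValueError("n_channels must be >= ring_channels")
        if self.pad_electrodes > self.ring_channels:
            raise ValueError("electrode padding cannot exceed the ring size")
        if min(self.block1_channels, self.post_concat_channels,
               self.sepconv_channels) < 1:
            raise ValueError("all channel counts must be >= 1")
        t, e = self.spatial_trace()[-1]
        if t < 1 or e < 1:
            raise ValueError(
                f"window_len={self.window_len} / temporal_pool={self.temporal_pool} "
                "collapse the feature map to zero extent; use a longer window or "
                "a smaller temporal pool")


# ---------------------------------------------------------------------------
# circular-8 padding
# ---------------------------------------------------------------------------

def circular8_pad(x, pad_time: int, pad_elec: int, ring: int = 8):
    """Pad an NCHW tensor (H=time, W=electrodes) for the opening convolution.

    The time axis is zero-padded ``pad_time`` per side. On the electrode
    axis the *leading* side wraps the tail of the circular ring block
    (electrodes ``ring-pad_elec .. ring-1``) while the *trailing* side —
    beyond the ring — is zero-filled.
    """
    return _circular_pad(x, pad_time, pad_time, pad_elec, ring)


def _circular_pad(x, pad_top: int, pad_bot: int, pad_elec: int, ring: int):
    x = x if isinstance(x, Tensor) else Tensor(x)
    n_elec = x.shape[3]
    if n_elec < ring:
        raise ValueError(f"need at least {ring} electrodes, got {n_elec}")
    if pad_elec > ring:
        raise ValueError(f"pad_elec={pad_elec} exceeds ring size {ring}")
    if pad_top < 0 or pad_bot < 0 or pad_elec < 0:
        raise ValueError("padding must be nonnegative")
    N, C, T, E = x.shape
    out = np.zeros((N, C, T + pad_top + pad_bot, E + 2 * pad_elec),
                   dtype=x.dtype)
    out[:, :, pad_top:pad_top + T, pad_elec:pad_elec + E] = x.data
    if pad_elec:
        out[:, :, pad_top:pad_top + T, :pad_elec] = \
            x.data[:, :, :, ring - pad_elec:ring]

    def bwd(g):
        dx = g[:, :, pad_top:pad_top + T, pad_elec:pad_elec + E].copy()
        if pad_elec:
            dx[:, :, :, ring - pad_elec:ring] += g[:, :, pad_top:pad_top + T, :pad_elec]
        ad._accum(x, dx)

    return ad._make(out, (x,), bwd, x.requires_grad)


class CircularConv2d(Module):
    """Opening convolution: kernel ``kh × kw``, time zero-padded to preserve
    length, electrode axis circular-padded over the ring (no bias; batch
    norm follows immediately)."""

    def __init__(self, rng, out_ch, kh, kw=3, pad_elec=2, ring=8,
                 name="conv2d_circular8"):
        from .layers import _kaiming_uniform
        self.weight = Tensor(_kaiming_uniform(rng, (out_ch, 1, kh, kw), kh * kw),
                             requires_grad=True)
        self.kh, self.kw = kh, kw
        self.pad_elec, self.ring = pad_elec, ring
        self.name = name

    def forward(self, x, ctx):
        x = _circular_pad(x, (self.kh - 1) // 2, self.kh // 2,
                          self.pad_elec, self.ring)
        return ad.conv2d(x, self.weight, None)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _branch(rng, cfg: ModelConfig, k: int) -> Sequential:
    b1, act, rate = cfg.block1_channels, cfg.activation, cfg.dropout_rate
    return Sequential([
        CircularConv2d(rng, b1, k, 3, cfg.pad_electrodes, cfg.ring_channels),
        BatchNorm2d(b1),
        Activation(act),
        MaxPool2d(cfg.temporal_pool, 1, name="maxpool_temporal"),
        Dropout2d(rate),
        SeparableConv2d(rng, b1, 2 * b1),
        BatchNorm2d(2 * b1),
        Activation(act),
        MaxPool2d(2, 2),
        Dropout2d(rate),
    ])


class MultiBranch(Module):
    """Part 1: parallel multi-scale branches, concatenated on channels."""

    def __init__(self, branches: list[Sequential]):
        self.branches = branches
        self.name = "part1_multibranch"

    def forward(self, x, ctx, record=None):
        outs = []
        for i, br in enumerate(self.branches):
            rec = record if i == 0 else None
            outs.append(br(x, ctx, rec))
        y = ad.concat(outs, axis=1)
        if record is not None:
            record.append(("concatenate", tuple(y.shape)))
        return y

    def __call__(self, x, ctx, record=None):
        return self.forward(x, ctx, record)


def _head(rng, cfg: ModelConfig, n_out: int) -> Sequential:
    return Sequential([
        Linear(rng, cfg.flatten_width, 128, name="linear_hidden"),
        Activation(cfg.activation),
        Linear(rng, 128, n_out, name="linear_out"),
    ])


class MscnnModel:
    """Built multi-scale CNN with addressable parts and trainable flags."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed, 0x5EB0])
        act, rate = cfg.activation, cfg.dropout_rate
        self.part1 = MultiBranch([_branch(rng, cfg, k) for k in cfg.kernel_sizes])
        self.part2 = Sequential([
            Conv2d(rng, cfg.concat_channels, cfg.post_concat_channels, 1, 1,
                   name="conv2d_1x1"),
            Activation(act),
        ], name="part2")
        s = cfg.sepconv_channels
        self.part3 = Sequential([
            SeparableConv2d(rng, cfg.post_concat_channels, s),
            BatchNorm2d(s),
            Activation(act),
            MaxPool2d(2, 2),
            Dropout2d(rate),
            SeparableConv2d(rng, s, s),
            BatchNorm2d(s),
            Activation(act),
            MaxPool2d(2, 2),
            Dropout2d(rate),
            Flatten(),
        ], name="part3")
        self.part4 = _head(rng, cfg, cfg.n_classes)
        self.domain_head: Sequential | None = None
        self.trainable = {p: True for p in PART_NAMES}

    # -- structure ----------------------------------------------------
    def parts(self) -> dict[str, Module]:
        d = {"part1": self.part1, "part2": self.part2,
             "part3": self.part3, "part4": self.part4}
        if self.domain_head is not None:
            d["domain"] = self.domain_head
        return d

    def add_domain_head(self, n_subjects: int) -> None:
        """Attach a subject-classification head identical in shape to Part 4.

        Its weights come from an RNG stream independent of the main parts,
        so models with and without the head share backbone initialisation.
        """
        rng = np.random.default_rng([self.cfg.seed, 0xD0_0D])
        self.domain_head = _head(rng, self.cfg, n_subjects)
        self.trainable["domain"] = True

    def set_trainable(self, flags: dict[str, bool]) -> None:
        for k, v in flags.items():
            if k not in self.trainable:
                raise KeyError(f"unknown part {k!r}")
            self.trainable[k] = bool(v)

    def parameters(self, parts=None, trainable_only=False) -> list[Tensor]:
        sel = self.parts()
        if parts is not None:
            parts = [_canon_part(p) for p in parts]
            sel = {k: v for k, v in sel.items() if k in parts}
        if trainable_only:
            sel = {k: v for k, v in sel.items() if self.trainable.get(k)}
        out = []
        for m in sel.values():
            out.extend(m.parameters())
        return out

    def clone(self) -> "MscnnModel":
        return copy.deepcopy(self)

    # -- forward passes -----------------------------------------------
    def _to_nchw(self, x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 3:  # (N, L, C) raw windows
            x = x[:, None, :, :]
        return Tensor(x)

    def part2_output(self, x, ctx: Context, record=None) -> Tensor:
        h = self.part1(self._to_nchw(x), ctx, record)
        return self.part2(h, ctx, record)

    def features(self, x, ctx: Context, record=None) -> Tensor:
        """Flatten-layer embedding (output of Part 3)."""
        return self.part3(self.part2_output(x, ctx, record), ctx, record)

    def features_from_part2(self, h, ctx: Context) -> Tensor:
        return self.part3(h if isinstance(h, Tensor) else Tensor(np.asarray(h, DTYPE)), ctx)

    def forward(self, x, ctx: Context, domain_lambda: float | None = None,
                record=None):
        """Class logits; with ``domain_lambda`` set (and a domain head
        attached) also subject logits through gradient reversal."""
        feat = self.features(x, ctx, record)
        logits = self.part4(feat, ctx, record)
        if domain_lambda is None:
            return logits
        if self.domain_head is None:
            raise ValueError("domain head not attached; call add_domain_head()")
        dlogits = self.domain_head(gradient_reversal(feat, domain_lambda), ctx)
        return logits, dlogits

    def head_logits(self, feat, ctx: Context) -> Tensor:
        return self.part4(feat if isinstance(feat, Tensor)
                          else Tensor(np.asarray(feat, DTYPE)), ctx)

    def predict_proba(self, windows, batch_size: int = 512) -> np.ndarray:
        """Eval-mode class probabilities for raw windows (N, L, C)."""
        ctx = Context(training=False)
        out = []
        for i in range(0, len(windows), batch_size):
            logits = self.forward(windows[i:i + batch_size], ctx)
            out.append(ad.softmax(logits.data))
        return np.concatenate(out, axis=0)

    def predict(self, windows, batch_size: int = 512) -> np.ndarray:
        return self.predict_proba(windows, batch_size).argmax(axis=1)


def build_mscnn(cfg: ModelConfig) -> MscnnModel:
    """Construct the four-part model; deterministic given ``cfg.seed``."""
    return MscnnModel(cfg)


# ---------------------------------------------------------------------------
# introspection
# ---------------------------------------------------------------------------

def infer_shapes(model: MscnnModel, cfg: ModelConfig | None = None):
    """(layer name, output shape) for a symbolic single-window forward pass.

    Part-1 rows are reported once (the five parallel branches share all
    shapes); the channel axis of the concatenation row carries the ×5
    multiplicity.
    """
    cfg = cfg or model.cfg
    record: list[tuple[str, tuple]] = []
    x = np.zeros((1, 1, cfg.window_len, cfg.n_channels), dtype=DTYPE)
    ctx = Context(training=False)
    model.forward(x, ctx, record=record)
    return record


def _canon_part(p) -> str:
    if isinstance(p, int):
        return f"part{p}"
    p = str(p).lower()
    return p if p.startswith(("part", "domain")) else f"part{p}"


def count_trainable(model: MscnnModel, parts=None) -> int:
    """Number of trainable parameters over the requested parts.

    ``parts`` entries may be ints (1–4) or names incl. ``"domain"``; parts
    whose trainable flag is cleared contribute nothing. With ``parts=None``
    all flagged-trainable parts are counted.
    """
    if parts is not None and len(list(parts)) == 0:
        warnings.warn("empty part subset; count is 0")
        return 0
    return int(sum(p.size for p in model.parameters(parts=parts,
                                                    trainable_only=True)))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def _state_arrays(model: MscnnModel) -> dict[str, np.ndarray]:
    out = {}
    for pname, mod in model.parts().items():
        stack = [(pname, mod)]
        while stack:
            prefix, m = stack.pop()
            for attr, v in sorted(vars(m).items()):
                key = f"{prefix}.{attr}"
                if isinstance(v, Tensor):
                    out[key] = v.data
                elif isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    stack.append((key, v))
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            stack.append((f"{key}.{i}", item))
    return out


def save_checkpoint(model: MscnnModel, path) -> None:
    """Single-file weight archive with the embedded architecture config."""
    arrays = _state_arrays(model)
    meta = {"config": asdict(model.cfg), "trainable": model.trainable,
            "n_domain": (None if model.domain_head is None
                         else model.domain_head.layers[2].bias.size)}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> MscnnModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = MscnnModel(ModelConfig(**meta["config"]))
        if meta["n_domain"]:
            model.add_domain_head(int(meta["n_domain"]))
        target = _state_arrays(model)
        for k, arr in target.items():
            arr[...] = z[k]
        model.trainable.update(meta["trainable"])
    return model
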