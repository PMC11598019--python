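"""Layer modules and the Adam optimizer built on :mod:`semgnet.autodiff`.

Layers are lightweight objects holding :class:`~semgnet.autodiff.Tensor`
parameters; the forward pass threads a :class:`Context` carrying the
training flag and the RNG used by dropout. There is no global mode state,
so the same model can be run in train and eval mode concurrently.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32

_ACTIVATIONS = ("relu", "leaky_relu", "elu")


class Context:
    """Per-call state for a forward pass."""

    def __init__(self, training: bool = False,
                 rng: np.random.Generator | None = None):
        self.training = training
        self.rng = rng if rng is not None else np.random.default_rng(0)


def activation(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return ad.leaky_relu(x, 0.0)
    if name == "leaky_relu":
        return ad.leaky_relu(x, 0.01)
    if name == "elu":
        # elu(x) = x if x>0 else exp(x)-1 ; composed from primitives
        pos = ad.leaky_relu(x, 0.0)
        neg = ad.sub(x, pos)  # min(x, 0)
        return ad.add(pos, Tensor(np.expm1(np.minimum(neg.data, 0.0))))
    raise ValueError(f"unknown activation {name!r}; expected one of {_ACTIVATIONS}")


class Module:
    name: str = ""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def forward(self, x: Tensor, ctx: Context) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: Tensor, ctx: Context) -> Tensor:
        return self.forward(x, ctx)


class Sequential(Module):
    def __init__(self, layers: list[Module], name: str = ""):
        self.layers = list(layers)
        self.name = name

    def forward(self, x: Tensor, ctx: Context, record: list | None = None) -> Tensor:
        for layer in self.layers:
            x = layer(x, ctx)
            if record is not None:
                record.append((layer.name, tuple(x.shape)))
        return x

    def __call__(self, x, ctx, record=None):
        return self.forward(x, ctx, record)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Stride-1 2-D convolution with explicit zero padding."""

    def __init__(self, rng, in_ch, out_ch, kh, kw, pad=(0, 0, 0, 0),
                 bias=True, name="conv2d"):
        fan_in = in_ch * kh * kw
        self.weight = Tensor(_kaiming_uniform(rng, (out_ch, in_ch, kh, kw), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None
        self.pad = pad  # (top, bottom, left, right)
        self.name = name

    def forward(self, x, ctx):
        if any(self.pad):
            x = ad.pad2d(x, *self.pad)
        return ad.conv2d(x, self.weight, self.bias)


class SeparableConv2d(Module):
    """Depthwise k×k (no bias) followed by pointwise 1×1 (with bias).

    Padding preserves the spatial extent, so the declared feature-map sizes
    of the architecture table hold at every stage.
    """

    def __init__(self, rng, in_ch, out_ch, k=3, name="separable_conv2d"):
        self.depthwise = Tensor(_kaiming_uniform(rng, (in_ch, k, k), k * k),
                                requires_grad=True)
        self.pointwise = Tensor(_kaiming_uniform(rng, (out_ch, in_ch, 1, 1), in_ch),
                                requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
        self.k = k
        self.name = name

    def forward(self, x, ctx):
        k = self.k
        x = ad.pad2d(x, (k - 1) // 2, k // 2, (k - 1) // 2, k // 2)
        x = ad.depthwise_conv2d(x, self.depthwise)
        return ad.conv2d(x, self.pointwise, self.bias)


class BatchNorm2d(Module):
    def __init__(self, n_ch, momentum=0.1, eps=1e-5, name="batchnorm2d"):
        self.gamma = Tensor(np.ones(n_ch, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=DTYPE)
        self.running_var = np.ones(n_ch, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.name = name

    def forward(self, x, ctx):
        return ad.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, training=ctx.training,
                              momentum=self.momentum, eps=self.eps)


class MaxPool2d(Module):
    def __init__(self, ph, pw, name="maxpool2d"):
        self.ph, self.pw = ph, pw
        self.name = name

    def forward(self, x, ctx):
        return ad.maxpool2d(x, self.ph, self.pw)


class Dropout2d(Module):
    def __init__(self, rate=0.2, name="dropout2d"):
        self.rate = rate
        self.name = name

    def forward(self, x, ctx):
        return ad.dropout(x, self.rate, ctx.rng, training=ctx.training,
                          channelwise=True)


class Activation(Module):
    def __init__(self, kind, name="activation"):
        if kind not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind
        self.name = name

    def forward(self, x, ctx):
        return activation(x, self.kind)


class Flatten(Module):
    def __init__(self, name="flatten"):
        self.name = name

    def forward(self, x, ctx):
        return ad.reshape(x, (x.shape[0], -1))


class Linear(Module):
    def __init__(self, rng, in_f, out_f, name="linear"):
        self.weight = Tensor(_kaiming_uniform(rng, (in_f, out_f), in_f),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_f, dtype=DTYPE), requires_grad=True)
        self.name = name

    def forward(self, x, ctx):
        return ad.add(ad.matmul(x, self.weight), self.bias)


class SGD:
    def __init__(self, params: list[Tensor], lr=1e-3, momentum=0.9,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.dtype, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam:
    """Adam with optional decoupled L2 weight decay; tracks state per
    parameter identity so frozen parameters can be excluded up front."""

    def __init__(self, params: list[Tensor], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.dtype, copy=False)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
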