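"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it
on a tape; ``backward()`` on a scalar loss walks the tape in reverse
topological order and accumulates gradients. Only the primitives needed for
the multi-scale CNN are implemented, each with a hand-written adjoint:
broadcast arithmetic, matmul, leaky-ReLU, sqrt, reductions, reshape/concat,
2-D convolution (dense and depthwise, via im2col), non-overlapping max
pooling, batch normalisation, dropout, zero/circular padding, a gradient
reversal operator and fused softmax cross-entropy.

Every adjoint is checked against central finite differences in the test
suite; keep new primitives covered the same way.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "scale", "matmul", "leaky_relu", "sqrt",
    "tsum", "tmean", "reshape", "concat", "dropout", "pad2d",
    "conv2d", "depthwise_conv2d", "maxpool2d", "batchnorm2d",
    "gradient_reversal", "softmax_cross_entropy", "softmax",
]


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- graph --------------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go; leaves keep their grads
            node._backward = None
            node._parents = ()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents, backward, requires_grad) -> Tensor:
    out = Tensor(data, requires_grad=requires_grad)
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data, dtype=g.dtype)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs_grad(a, b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), bwd, req)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs_grad(a, b)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, -_unbroadcast(g, b.shape))

    return _make(a.data - b.data, (a, b), bwd, req)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs_grad(a, b)

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), bwd, req)


def scale(a, c: float) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, g * c)

    return _make(a.data * c, (a,), bwd, a.requires_grad)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs_grad(a, b)

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bwd, req)


def leaky_relu(x, slope: float = 0.01) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = np.where(mask, x.data, x.data * slope)

    def bwd(g):
        _accum(x, np.where(mask, g, g * slope))

    return _make(out, (x,), bwd, x.requires_grad)


def sqrt(x, eps: float = 0.0) -> Tensor:
    x = _as_tensor(x)
    out = np.sqrt(x.data + eps)

    def bwd(g):
        _accum(x, g * (0.5 / np.maximum(out, np.finfo(out.dtype).tiny)))

    return _make(out, (x,), bwd, x.requires_grad)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(x, axis=None) -> Tensor:
    x = _as_tensor(x)
    out = x.data.sum(axis=axis)

    def bwd(g):
        if axis is None:
            _accum(x, np.broadcast_to(g, x.shape).copy())
        else:
            _accum(x, np.broadcast_to(np.expand_dims(g, axis), x.shape).copy())

    return _make(out, (x,), bwd, x.requires_grad)


def tmean(x, axis=None) -> Tensor:
    x = _as_tensor(x)
    n = x.size if axis is None else x.shape[axis]
    return scale(tsum(x, axis=axis), 1.0 / n)


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    orig = x.shape

    def bwd(g):
        _accum(x, g.reshape(orig))

    return _make(x.data.reshape(shape), (x,), bwd, x.requires_grad)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    req = _needs_grad(*tensors)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, bwd, req)


# ---------------------------------------------------------------------------
# regularisation / domain adaptation operators
# ---------------------------------------------------------------------------

def dropout(x, rate: float, rng: np.random.Generator,
            training: bool = True, channelwise: bool = True) -> Tensor:
    """Inverted dropout; with ``channelwise`` whole feature maps are dropped
    (Dropout2d semantics for NCHW input)."""
    x = _as_tensor(x)
    if not training or rate <= 0.0:
        return x
    if channelwise and x.data.ndim == 4:
        mshape = (x.shape[0], x.shape[1], 1, 1)
    else:
        mshape = x.shape
    keep = (rng.random(mshape) >= rate).astype(x.dtype) / (1.0 - rate)

    def bwd(g):
        _accum(x, g * keep)

    return _make(x.data * keep, (x,), bwd, x.requires_grad)


def gradient_reversal(x, lam: float) -> Tensor:
    """Identity forward; backward multiplies the upstream gradient by -lam."""
    if lam < 0:
        raise ValueError(f"gradient reversal strength must be >= 0, got {lam}")
    x = _as_tensor(x)

    def bwd(g):
        _accum(x, g * (-lam))

    return _make(x.data.copy(), (x,), bwd, x.requires_grad)


# ---------------------------------------------------------------------------
# padding
# ---------------------------------------------------------------------------

def pad2d(x, top: int, bottom: int, left: int, right: int) -> Tensor:
    """Zero-pad the last two axes of an NCHW tensor."""
    x = _as_tensor(x)
    out = np.pad(x.data, ((0, 0), (0, 0), (top, bottom), (left, right)))
    H, W = x.shape[2], x.shape[3]

    def bwd(g):
        _accum(x, g[:, :, top:top + H, left:left + W])

    return _make(out, (x,), bwd, x.requires_grad)


# ---------------------------------------------------------------------------
# convolution & pooling (stride-1 conv, non-overlapping pool: all the model uses)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # x: (N,C,H,W) -> (N, oH, oW, C, kh, kw) view then packed copy
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # v: (N, C, oH, oW, kh, kw)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))


def _col2im_add(dcols: np.ndarray, xshape: tuple, kh: int, kw: int) -> np.ndarray:
    # dcols: (N, oH, oW, C, kh, kw) -> dx (N,C,H,W)
    N, C, H, W = xshape
    oH, oW = H - kh + 1, W - kw + 1
    dx = np.zeros(xshape, dtype=dcols.dtype)
    d = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N,C,oH,oW,kh,kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + oH, j:j + oW] += d[:, :, :, :, i, j]
    return dx


def conv2d(x, w, b=None) -> Tensor:
    """Valid, stride-1 cross-correlation. x:(N,C,H,W) w:(O,C,kh,kw) b:(O,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    O, C, kh, kw = w.shape
    N = x.shape[0]
    oH, oW = x.shape[2] - kh + 1, x.shape[3] - kw + 1
    cols = _im2col(x.data, kh, kw).reshape(N * oH * oW, C * kh * kw)
    wmat = w.data.reshape(O, C * kh * kw)
    out = (cols @ wmat.T).reshape(N, oH, oW, O).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    req = _needs_grad(*parents)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(N * oH * oW, O)
        if w.requires_grad:
            _accum(w, (gmat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, oH, oW, C, kh, kw)
            _accum(x, _col2im_add(dcols, x.shape, kh, kw))

    return _make(out, parents, bwd, req)


def depthwise_conv2d(x, w) -> Tensor:
    """Per-channel valid stride-1 convolution. x:(N,C,H,W) w:(C,kh,kw)."""
    x, w = _as_tensor(x), _as_tensor(w)
    C, kh, kw = w.shape
    N = x.shape[0]
    oH, oW = x.shape[2] - kh + 1, x.shape[3] - kw + 1
    cols = _im2col(x.data, kh, kw)  # (N,oH,oW,C,kh,kw)
    out = np.einsum("nhwcij,cij->nchw", cols, w.data, optimize=True)
    req = _needs_grad(x, w)

    def bwd(g):
        if w.requires_grad:
            _accum(w, np.einsum("nhwcij,nchw->cij", cols, g, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("nchw,cij->nhwcij", g, w.data, optimize=True)
            _accum(x, _col2im_add(dcols, x.shape, kh, kw))

    return _make(out, (x, w), bwd, req)


def maxpool2d(x, ph: int, pw: int) -> Tensor:
    """Non-overlapping max pool; trailing rows/cols that do not fill a full
    window are cropped (floor semantics)."""
    x = _as_tensor(x)
    N, C, H, W = x.shape
    oH, oW = H // ph, W // pw
    xc = x.data[:, :, :oH * ph, :oW * pw]
    r = xc.reshape(N, C, oH, ph, oW, pw)
    out = r.max(axis=(3, 5))
    # argmax over the ph*pw window, for gradient routing
    flat = r.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, oH, oW, ph * pw)
    arg = flat.argmax(axis=-1)

    def bwd(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dxc = dflat.reshape(N, C, oH, oW, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros_like(x.data)
        dx[:, :, :oH * ph, :oW * pw] = dxc.reshape(N, C, oH * ph, oW * pw)
        _accum(x, dx)

    return _make(out, (x,), bwd, x.requires_grad)


def batchnorm2d(x, gamma, beta, running_mean, running_var,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N,H,W) per channel. ``running_*`` arrays are
    updated in place during training and used verbatim in eval mode."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    req = _needs_grad(x, gamma, beta)

    def bwd(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
            if training:
                m = x.shape[0] * x.shape[2] * x.shape[3]
                gm = g.mean(axis=(0, 2, 3), keepdims=True)
                gxm = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                _accum(x, gi * (g - gm - xhat * gxm))
                del m
            else:
                _accum(x, gi * g)

    return _make(out, (x, gamma, beta), bwd, req)


# ---------------------------------------------------------------------------
# loss heads
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.shape[0]
    p = softmax(logits.data)
    eps = np.finfo(p.dtype).tiny
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))

    def bwd(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        _accum(logits, g * d / n)

    return _make(np.asarray(loss, dtype=logits.dtype), (logits,), bwd,
                 logits.requires_grad)
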