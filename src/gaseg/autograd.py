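"""A minimal define-by-run reverse-mode autodiff engine on NumPy arrays.

Supports exactly the operations the 3D-to-2D segmentation network needs:
element-wise arithmetic, ReLU/sigmoid/softmax, axis reductions, 2x pooling
and upsampling, channel concatenation, 'same' convolutions (via the kernels
in :mod:`gaseg._conv`) and numerically stable binary cross-entropy on
logits. Everything is float32.

Each operation builds a node holding references to its parents and a closure
that propagates the upstream gradient; :meth:`Tensor.backward` runs a
topological sweep. Gradients only flow into branches that contain at least
one tensor with ``requires_grad`` set, so constant inputs cost nothing.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from . import _conv

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "relu", "sigmoid", "log", "softmax",
    "tsum", "tmean", "concat", "conv3d", "conv2d",
    "avg_pool3d", "avg_pool2d", "upsample2d", "bce_with_logits",
    "AdamW",
]


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    # note: np.ascontiguousarray would promote 0-d scalars to 1-d
    return a if a.flags.c_contiguous else np.ascontiguousarray(a)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd", "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _bwd: Optional[Callable[[np.ndarray], None]] = None):
        self.data = _as_f32(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._bwd = _bwd
        self._grad_borrowed = False

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # First accumulation borrows the array (no copy); a second one
        # allocates, so borrowed gradients are never mutated in place (the
        # same array may have been handed to several parents).
        if self.grad is None:
            self.grad = np.asarray(g, np.float32)
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # convenience operators (scalar or Tensor operands)
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return mul(self, _wrap(-1.0))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient g back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _bwd=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _bwd=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _bwd=bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return Tensor(out_data, _parents=(a, b), _bwd=bwd)


def _leaky_fwd(x: np.ndarray, slope: float) -> np.ndarray:
    if slope == 0.0:
        return np.maximum(x, np.float32(0.0))
    return np.where(x > 0, x, np.float32(slope) * x)


def _leaky_bwd(g: np.ndarray, out: np.ndarray, slope: float) -> np.ndarray:
    if slope == 0.0:
        return g * (out > 0)
    return g * np.where(out > 0, np.float32(1.0), np.float32(slope))


def add_relu(a: Tensor, b: Tensor, slope: float = 0.0) -> Tensor:
    """Fused (leaky-)relu(a + b) for residual shortcuts (same shapes)."""
    assert a.data.shape == b.data.shape
    out_data = _leaky_fwd(a.data + b.data, slope)

    def bwd(g):
        gm = _leaky_bwd(g, out_data, slope)
        if a.requires_grad:
            a._accum(gm)
        if b.requires_grad:
            b._accum(gm)

    return Tensor(out_data, _parents=(a, b), _bwd=bwd)


def relu(a: Tensor, slope: float = 0.0) -> Tensor:
    """Rectifier; ``slope`` > 0 gives the leaky variant (no dead units)."""
    out_data = _leaky_fwd(a.data, slope)

    def bwd(g):
        if a.requires_grad:
            a._accum(_leaky_bwd(g, out_data, slope))

    return Tensor(out_data, _parents=(a,), _bwd=bwd)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        if a.requires_grad:
            a._accum(g * s * (1.0 - s))

    return Tensor(s, _parents=(a,), _bwd=bwd)


def log(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return Tensor(out_data, _parents=(a,), _bwd=bwd)


def softmax(a: Tensor, axis: int) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - dot))

    return Tensor(s, _parents=(a,), _bwd=bwd)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
            return
        gg = g
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.data.ndim for ax in axes):
                gg = np.expand_dims(gg, ax)
        a._accum(np.broadcast_to(gg, a.data.shape))

    return Tensor(out_data, _parents=(a,), _bwd=bwd)


def tmean(a: Tensor) -> Tensor:
    n = float(a.data.size)
    return mul(tsum(a), _wrap(1.0 / n))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _bwd=bwd)


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           fuse_relu: bool = False, slope: float = 0.0) -> Tensor:
    out_data, cache = _conv.conv3d_forward(x.data, w.data)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    if fuse_relu:
        out_data = _leaky_fwd(out_data, slope)

    def bwd(g):
        g = _as_f32(g)
        if fuse_relu:
            g = _leaky_bwd(g, out_data, slope)
        dw, dx = _conv.conv3d_backward(x.data, w.data, g, cache, x.requires_grad)
        if w.requires_grad:
            w._accum(dw)
        if x.requires_grad and dx is not None:
            x._accum(dx)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _bwd=bwd)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           fuse_relu: bool = False, slope: float = 0.0) -> Tensor:
    out_data = _conv.conv2d_forward(x.data, w.data)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)
    if fuse_relu:
        out_data = _leaky_fwd(out_data, slope)

    def bwd(g):
        g = _as_f32(g)
        if fuse_relu:
            g = _leaky_bwd(g, out_data, slope)
        dw, dx = _conv.conv2d_backward(x.data, w.data, g, x.requires_grad)
        if w.requires_grad:
            w._accum(dw)
        if x.requires_grad and dx is not None:
            x._accum(dx)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, _parents=parents, _bwd=bwd)


def weighted_z_sum(x: Tensor, alpha: Tensor) -> Tensor:
    """Attention-weighted reduction over the axial axis.

    ``x`` is (N, C, Z, X, Y); ``alpha`` is (N, 1, Z, X, Y) (softmaxed over
    z). Returns (N, C, X, Y). Fused kernels avoid the full-size product
    temporary of the naive mul-then-sum formulation.
    """
    a = np.ascontiguousarray(alpha.data[:, 0])
    N, C, Z, X, Y = x.data.shape
    out_data = np.empty((N, C, X, Y), np.float32)
    _conv._nb_wsum_fwd(x.data, a, out_data)

    def bwd(g):
        g = _as_f32(g)
        if x.requires_grad:
            dx = np.empty_like(x.data)
            _conv._nb_wsum_dx(a, g, dx)
            x._accum(dx)
        if alpha.requires_grad:
            da = np.empty((N, Z, X, Y), np.float32)
            _conv._nb_wsum_da(x.data, g, da)
            alpha._accum(da[:, None])

    return Tensor(out_data, _parents=(x, alpha), _bwd=bwd)


def avg_pool3d(x: Tensor, factor: tuple[int, int, int]) -> Tensor:
    N, C, Z, X, Y = x.data.shape
    fz, fx, fy = factor
    assert Z % fz == 0 and X % fx == 0 and Y % fy == 0, "pool factor must divide dims"
    r = x.data.reshape(N, C, Z // fz, fz, X // fx, fx, Y // fy, fy)
    out_data = r.mean(axis=(3, 5, 7))
    scale = np.float32(1.0 / (fz * fx * fy))

    def bwd(g):
        if not x.requires_grad:
            return
        gg = (g * scale)[:, :, :, None, :, None, :, None]
        x._accum(np.broadcast_to(gg, r.shape).reshape(x.data.shape))

    return Tensor(out_data, _parents=(x,), _bwd=bwd)


def avg_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    N, C, X, Y = x.data.shape
    f = factor
    assert X % f == 0 and Y % f == 0
    r = x.data.reshape(N, C, X // f, f, Y // f, f)
    out_data = r.mean(axis=(3, 5))
    scale = np.float32(1.0 / (f * f))

    def bwd(g):
        if not x.requires_grad:
            return
        gg = (g * scale)[:, :, :, None, :, None]
        x._accum(np.broadcast_to(gg, r.shape).reshape(x.data.shape))

    return Tensor(out_data, _parents=(x,), _bwd=bwd)


def upsample2d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour 2x upsampling of (N, C, X, Y)."""
    f = factor
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def bwd(g):
        if not x.requires_grad:
            return
        N, C, Xo, Yo = g.shape
        x._accum(g.reshape(N, C, Xo // f, f, Yo // f, f).sum(axis=(3, 5)))

    return Tensor(out_data, _parents=(x,), _bwd=bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise binary cross-entropy from logits (numerically stable)."""
    t = _as_f32(targets)
    z = logits.data
    # log(1 + exp(-|z|)) + max(z, 0) - z*t
    out_data = np.logaddexp(0.0, -np.abs(z)).astype(np.float32) + np.maximum(z, 0) - z * t

    def bwd(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * (p - t))

    return Tensor(out_data, _parents=(logits,), _bwd=bwd)


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied only to convolution weights, not biases; biases
    are recognised as 1-D parameters.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 5e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay and p.data.ndim > 1:
                p.data *= np.float32(1.0 - self.lr * self.weight_decay)
            p.data -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
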