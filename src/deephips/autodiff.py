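"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operator set needed by the segmentation
network and its overlap losses: broadcasting arithmetic, reductions,
``log``/``exp``/``clip``, matrix multiplication, concatenation, slicing,
padding, and three volumetric primitives with hand-written adjoints
(``conv3d``, ``max_pool3d``, ``upsample3d``).

Gradients flow through a :class:`Tensor` graph built eagerly; calling
:meth:`Tensor.backward` runs a topological sweep. All data is kept in
float64 for reproducible CPU arithmetic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "max_pool3d", "upsample3d", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray is the left operand
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd machinery ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            self._accumulate(g @ other.data.swapaxes(-1, -2))
            other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._backward = bw
        return out

    # -- elementwise functions ------------------------------------------------
    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def clip(self, lo, hi):
        """Clamp values; gradient is zero outside [lo, hi] (projection rule)."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(old))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


# -- volumetric primitives ----------------------------------------------------
def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Shape-preserving 3-D convolution (cross-correlation), stride 1.

    x: (C_in, D, H, W); w: (C_out, C_in, k, k, k); b: (C_out,) or None.
    Computed as k^3 offset-wise matrix products, which keeps peak memory at
    one padded copy of the input instead of an im2col buffer.
    """
    cin, D, H, W = x.data.shape
    cout, cin_w, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if cin != cin_w:
        raise ValueError(f"conv3d channel mismatch: input {cin}, kernel {cin_w}")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3)
    n = D * H * W
    y = np.zeros((cout, n))

    def slab(dx, dy, dz):
        return np.ascontiguousarray(
            xp[:, dx : dx + D, dy : dy + H, dz : dz + W]
        ).reshape(cin, n)

    for dx in range(k):
        for dy in range(k):
            for dz in range(k):
                y += w.data[:, :, dx, dy, dz] @ slab(dx, dy, dz)
    if b is not None:
        y += b.data[:, None]
    out = Tensor(
        y.reshape(cout, D, H, W),
        _parents=(x, w) if b is None else (x, w, b),
    )

    def bw(g):
        gm = g.reshape(cout, n)
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=1))
        gw = np.empty_like(w.data) if w.requires_grad else None
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for dx in range(k):
            for dy in range(k):
                for dz in range(k):
                    if gw is not None:
                        gw[:, :, dx, dy, dz] = gm @ slab(dx, dy, dz).T
                    if gxp is not None:
                        gxp[:, dx : dx + D, dy : dy + H, dz : dz + W] += (
                            w.data[:, :, dx, dy, dz].T @ gm
                        ).reshape(cin, D, H, W)
        if gw is not None:
            w._accumulate(gw)
        if gxp is not None:
            x._accumulate(
                gxp[:, pad : pad + D, pad : pad + H, pad : pad + W]
                if pad
                else gxp
            )

    out._backward = bw
    return out


def channel_batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-3):
    """Fused per-channel batch normalization over the spatial axes.

    x: (C, D, H, W); gamma, beta: (C,). Returns (out, mean, var) with the
    batch statistics as plain arrays. The backward pass uses the closed
    form for the statistics' dependence on the input.
    """
    c = x.data.shape[0]
    xr = x.data.reshape(c, -1)
    n = xr.shape[1]
    mu = xr.mean(axis=1)
    var = xr.var(axis=1)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xr - mu[:, None]) * inv[:, None]
    y = gamma.data[:, None] * xhat + beta.data[:, None]
    out = Tensor(y.reshape(x.data.shape), _parents=(x, gamma, beta))

    def bw(g):
        gr = g.reshape(c, n)
        if beta.requires_grad:
            beta._accumulate(gr.sum(axis=1))
        gxh_mean = (gr * xhat).mean(axis=1)
        if gamma.requires_grad:
            gamma._accumulate(gxh_mean * n)
        if x.requires_grad:
            gx = (gamma.data * inv)[:, None] * (
                gr - gr.mean(axis=1)[:, None] - xhat * gxh_mean[:, None]
            )
            x._accumulate(gx.reshape(x.data.shape))

    out._backward = bw
    return out, mu, var


def max_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling; ties share the gradient equally."""
    c, D, H, W = x.data.shape
    f = factor
    if D % f or H % f or W % f:
        raise ValueError(f"spatial dims {x.data.shape[1:]} not divisible by {f}")
    blocks = x.data.reshape(c, D // f, f, H // f, f, W // f, f)
    pooled = blocks.max(axis=(2, 4, 6))
    out = Tensor(pooled, _parents=(x,))

    def bw(g):
        mask = blocks == pooled[:, :, None, :, None, :, None]
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        gb = mask * (g[:, :, None, :, None, :, None] / counts)
        x._accumulate(gb.reshape(x.data.shape))

    out._backward = bw
    return out


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Repeat-upsampling (each voxel becomes a factor^3 block)."""
    f = factor
    y = np.repeat(np.repeat(np.repeat(x.data, f, axis=1), f, axis=2), f, axis=3)
    out = Tensor(y, _parents=(x,))

    def bw(g):
        c, D, H, W = x.data.shape
        gb = g.reshape(c, D, f, H, f, W, f).sum(axis=(2, 4, 6))
        x._accumulate(gb)

    out._backward = bw
    return out
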