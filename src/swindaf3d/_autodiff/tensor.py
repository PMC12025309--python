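"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it on a tape of parent links; :meth:`Tensor.backward` walks the tape
in reverse topological order accumulating vector-Jacobian products.  Only the
operations needed by the segmentation networks in this package are provided;
all of them are closed over float32 so a whole training step allocates no
float64 temporaries.

Shapes are channels-last throughout the package: a feature grid is
``(H, W, D, C)``, which lets every convolution and projection run as a single
BLAS matmul over the trailing axis.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_F32 = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _F32:
        a = a.astype(_F32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.astype(_F32, copy=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray, own: bool = False):
        """Add ``g`` to this node's gradient.

        ``own=True`` promises that ``g`` is a freshly allocated array no other
        node will see, so it can be stored without a defensive copy.
        """
        if self.grad is None:
            if own and g.base is None and g.dtype == _F32:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=_F32)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free the graph as we go: closures capture their outputs,
                # forming reference cycles that would otherwise pin every
                # intermediate array until a full gc pass
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), own=True)
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), own=True)

    out._backward = backward
    return out


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data ** _F32(p), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * _F32(p) * a.data ** _F32(p - 1.0), own=True)

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape), own=True)
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape), own=True)

    out._backward = backward
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims, dtype=_F32), parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(_F32, copy=False))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(_F32, copy=False))

    out._backward = backward
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    out._backward = backward
    return out


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    out._backward = backward
    return out


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.data[idx], parents=(a,))

    def backward(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            ga[idx] = g  # basic (slice) indexing only: no repeated positions
            a._accumulate(ga, own=True)

    out._backward = backward
    return out


def pad(a, pad_width) -> Tensor:
    """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
    a = as_tensor(a)
    out = Tensor(np.pad(a.data, pad_width), parents=(a,))
    slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, a.data.shape))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[slices])

    out._backward = backward
    return out


def roll(a, shifts, axes) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.roll(a.data, shifts, axes), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.roll(g, tuple(-s for s in shifts), axes), own=True)

    out._backward = backward
    return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    out._backward = backward
    return out


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out.data, own=True)

    out._backward = backward
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data, own=True)

    out._backward = backward
    return out


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.sqrt(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * _F32(0.5) / out.data, own=True)

    out._backward = backward
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.tanh(a.data), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - out.data * out.data), own=True)

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out.data * (1.0 - out.data), own=True)

    out._backward = backward
    return out


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclamped entries."""
    a = as_tensor(a)
    out = Tensor(np.clip(a.data, lo, hi), parents=(a,))
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * inside, own=True)

    out._backward = backward
    return out


def gelu(a) -> Tensor:
    """Exact Gaussian-error GELU: x * Phi(x)."""
    a = as_tensor(a)
    phi_cdf = ndtr(a.data).astype(_F32)
    out = Tensor(a.data * phi_cdf, parents=(a,))

    def backward(g):
        if a.requires_grad:
            pdf = _F32(1.0 / np.sqrt(2 * np.pi)) * np.exp(_F32(-0.5) * a.data * a.data)
            a._accumulate(g * (phi_cdf + a.data * pdf), own=True)

    out._backward = backward
    return out


def prelu(a, alpha) -> Tensor:
    """Parametric ReLU with per-channel (trailing-axis) slope ``alpha``."""
    a, alpha = as_tensor(a), as_tensor(alpha)
    neg = a.data < 0
    out = Tensor(np.where(neg, alpha.data * a.data, a.data), parents=(a, alpha))

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.where(neg, alpha.data * g, g).astype(_F32, copy=False), own=True)
        if alpha.requires_grad:
            ga = np.where(neg, a.data * g, 0.0).astype(_F32, copy=False)
            alpha._accumulate(_unbroadcast(ga, alpha.data.shape), own=True)

    out._backward = backward
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out = Tensor(np.where(pos, a.data, 0.0).astype(_F32, copy=False), parents=(a,))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * pos, own=True)

    out._backward = backward
    return out


def softmax(a, axis=-1) -> Tensor:
    """Numerically stable softmax.

    Entries equal to ``-inf`` (attention masking) receive exactly zero weight.
    """
    a = as_tensor(a)
    x = a.data
    m = np.max(x, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(x - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(a,))

    def backward(g):
        if a.requires_grad:
            dot = (g * out.data).sum(axis=axis, keepdims=True)
            a._accumulate(out.data * (g - dot), own=True)

    out._backward = backward
    return out


def gather0(table, idx: np.ndarray) -> Tensor:
    """Row gather ``table[idx]`` along axis 0 (relative-position bias lookup)."""
    table = as_tensor(table)
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], parents=(table,))

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, idx.reshape(-1), g.reshape(-1, *table.data.shape[1:]))
            table._accumulate(gt, own=True)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# spatial operations (channels-last volumes)
# ---------------------------------------------------------------------------

def normalize(a, axes, eps: float = 1e-5) -> Tensor:
    """Fused zero-mean unit-variance normalisation over ``axes``.

    One tape node instead of the six a composed implementation would create;
    the backward pass uses the closed form
    ``dx = inv_std * (g - mean(g) - xn * mean(g * xn))`` over the pooled axes.
    """
    a = as_tensor(a)
    axes = tuple(axes) if isinstance(axes, (tuple, list)) else (axes,)
    mu = a.data.mean(axis=axes, keepdims=True, dtype=_F32)
    xc = a.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True, dtype=_F32)
    inv = 1.0 / np.sqrt(var + _F32(eps))
    xn = xc * inv
    out = Tensor(xn, parents=(a,))

    def backward(g):
        if not a.requires_grad:
            return
        gm = g.mean(axis=axes, keepdims=True, dtype=_F32)
        gxn = np.mean(g * xn, axis=axes, keepdims=True, dtype=_F32)
        a._accumulate(inv * (g - gm - xn * gxn), own=True)

    out._backward = backward
    return out


_OFFSETS_CACHE: dict[int, list] = {}


def conv3d(x, w, b=None, dilation: int = 1) -> Tensor:
    """'Same' 3D convolution of a ``(H, W, D, Cin)`` grid.

    ``w`` has shape ``(k, k, k, Cin, Cout)``; stride is 1 and zero padding is
    ``dilation * (k // 2)`` so output extents equal input extents.  The kernel
    loop runs as ``k**3`` GEMMs over the trailing channel axis, which keeps
    peak memory at one padded copy of the input.
    """
    x, w = as_tensor(x), as_tensor(w)
    k = w.data.shape[0]
    H, W, D, cin = x.data.shape
    cout = w.data.shape[-1]
    p = dilation * (k // 2)
    if p > 0:
        xp = np.pad(x.data, ((p, p), (p, p), (p, p), (0, 0)))
    else:
        xp = x.data
    offs = _OFFSETS_CACHE.setdefault(k, [(i, j, l) for i in range(k) for j in range(k) for l in range(k)])
    out_data = np.zeros((H, W, D, cout), dtype=_F32)
    out_flat = out_data.reshape(-1, cout)
    for (i, j, l) in offs:
        sl = xp[i * dilation:i * dilation + H,
                j * dilation:j * dilation + W,
                l * dilation:l * dilation + D]
        out_flat += np.ascontiguousarray(sl).reshape(-1, cin) @ w.data[i, j, l]
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    if b is not None:
        out_data += parents[2].data
    out = Tensor(out_data, parents=parents)

    def backward(g):
        gm = g.reshape(-1, cout)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for (i, j, l) in offs:
                sl = xp[i * dilation:i * dilation + H,
                        j * dilation:j * dilation + W,
                        l * dilation:l * dilation + D]
                gw[i, j, l] = sl.reshape(-1, cin).T @ gm
            w._accumulate(gw, own=True)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for (i, j, l) in offs:
                gxp[i * dilation:i * dilation + H,
                    j * dilation:j * dilation + W,
                    l * dilation:l * dilation + D] += (gm @ w.data[i, j, l].T).reshape(H, W, D, cin)
            if p > 0:
                gxp = gxp[p:-p, p:-p, p:-p]
            x._accumulate(gxp, own=True)
        if b is not None and parents[2].requires_grad:
            parents[2]._accumulate(_unbroadcast(g, parents[2].data.shape))

    out._backward = backward
    return out


def upsample2(x, axis: int) -> Tensor:
    """Double one spatial axis by linear interpolation (half-voxel aligned).

    Output sample ``2i`` is ``0.25*x[i-1] + 0.75*x[i]`` and ``2i+1`` is
    ``0.75*x[i] + 0.25*x[i+1]`` with edge clamping — the standard
    align_corners=False convention.
    """
    x = as_tensor(x)
    y = np.moveaxis(x.data, axis, 0)
    n = y.shape[0]
    lo = np.concatenate([y[:1], y[:-1]], axis=0)
    hi = np.concatenate([y[1:], y[-1:]], axis=0)
    out_m = np.empty((2 * n,) + y.shape[1:], dtype=_F32)
    out_m[0::2] = _F32(0.25) * lo + _F32(0.75) * y
    out_m[1::2] = _F32(0.75) * y + _F32(0.25) * hi
    out = Tensor(np.moveaxis(out_m, 0, axis), parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gm = np.moveaxis(g, axis, 0)
        ge, go = gm[0::2], gm[1::2]
        gx = _F32(0.75) * ge + _F32(0.75) * go
        # lo path: lo[i] = x[max(i-1, 0)] -> x[i] gains 0.25*ge[i+1]; x[0] also 0.25*ge[0]
        gx[:-1] += _F32(0.25) * ge[1:]
        gx[0] += _F32(0.25) * ge[0]
        # hi path: hi[i] = x[min(i+1, n-1)] -> x[i] gains 0.25*go[i-1]; x[-1] also 0.25*go[-1]
        gx[1:] += _F32(0.25) * go[:-1]
        gx[-1] += _F32(0.25) * go[-1]
        x._accumulate(np.ascontiguousarray(np.moveaxis(gx, 0, axis)), own=True)

    out._backward = backward
    return out


def maxpool2(x) -> Tensor:
    """2x2x2 max pooling of a ``(H, W, D, C)`` grid with even spatial extents."""
    x = as_tensor(x)
    H, W, D, C = x.data.shape
    if H % 2 or W % 2 or D % 2:
        raise ValueError("maxpool2 requires even spatial extents")
    blocks = x.data.reshape(H // 2, 2, W // 2, 2, D // 2, 2, C)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5, 6).reshape(H // 2, W // 2, D // 2, 8, C)
    arg = blocks.argmax(axis=3)
    out = Tensor(np.take_along_axis(blocks, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :],
                 parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gb = np.zeros((H // 2, W // 2, D // 2, 8, C), dtype=_F32)
        np.put_along_axis(gb, arg[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gb = gb.reshape(H // 2, W // 2, D // 2, 2, 2, 2, C).transpose(0, 3, 1, 4, 2, 5, 6)
        x._accumulate(np.ascontiguousarray(gb.reshape(H, W, D, C)), own=True)

    out._backward = backward
    return out
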