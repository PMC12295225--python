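"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is exactly what the model zoo
needs: broadcast arithmetic, (batched) matmul, 2-D convolution with groups /
strides / per-sample kernels, softmax, the usual activations, layer
statistics and shape surgery.  Everything is float64 by default so numerical
oracles in the test-suite can use tight tolerances.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if is_grad_enabled() and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None
                node._parents = ()

    def _accum(self, grad):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, _wrap(other)
        out = Tensor._make(a.data + b.data, (a, b), None)

        def bwd(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor._make(-a.data, (a,), None)
        out._backward = (lambda g: a._accum(-g)) if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, _wrap(other)
        out = Tensor._make(a.data * b.data, (a, b), None)

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _wrap(other)
        out = Tensor._make(a.data / b.data, (a, b), None)

        def bwd(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return _wrap(other) / self

    def __pow__(self, p: float):
        a = self
        out = Tensor._make(a.data ** p, (a,), None)
        out._backward = (
            (lambda g: a._accum(g * p * a.data ** (p - 1))) if out.requires_grad else None
        )
        return out

    def __matmul__(self, other):
        a, b = self, _wrap(other)
        out = Tensor._make(a.data @ b.data, (a, b), None)

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        a = self
        y = np.exp(a.data)
        out = Tensor._make(y, (a,), None)
        out._backward = (lambda g: a._accum(g * y)) if out.requires_grad else None
        return out

    def log(self):
        a = self
        out = Tensor._make(np.log(a.data), (a,), None)
        out._backward = (lambda g: a._accum(g / a.data)) if out.requires_grad else None
        return out

    def sqrt(self):
        a = self
        y = np.sqrt(a.data)
        out = Tensor._make(y, (a,), None)
        out._backward = (lambda g: a._accum(g / (2.0 * y))) if out.requires_grad else None
        return out

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor._make(y, (a,), None)
        out._backward = (lambda g: a._accum(g * y * (1.0 - y))) if out.requires_grad else None
        return out

    def tanh(self):
        a = self
        y = np.tanh(a.data)
        out = Tensor._make(y, (a,), None)
        out._backward = (lambda g: a._accum(g * (1.0 - y * y))) if out.requires_grad else None
        return out

    def relu(self):
        a = self
        mask = a.data > 0
        out = Tensor._make(a.data * mask, (a,), None)
        out._backward = (lambda g: a._accum(g * mask)) if out.requires_grad else None
        return out

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor._make(x * cdf, (a,), None)

        def bwd(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            a._accum(g * (cdf + x * pdf))

        out._backward = bwd if out.requires_grad else None
        return out

    def silu(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor._make(a.data * s, (a,), None)

        def bwd(g):
            a._accum(g * (s + a.data * s * (1.0 - s)))

        out._backward = bwd if out.requires_grad else None
        return out

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(y, (a,), None)

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accum(y * (g - dot))

        out._backward = bwd if out.requires_grad else None
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor._make(out_data, (a,), None)

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape surgery -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out = Tensor._make(a.data.reshape(shape), (a,), None)
        out._backward = (
            (lambda g: a._accum(g.reshape(a.data.shape))) if out.requires_grad else None
        )
        return out

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor._make(a.data.transpose(axes), (a,), None)
        out._backward = (
            (lambda g: a._accum(g.transpose(inv))) if out.requires_grad else None
        )
        return out

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.data.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    def __getitem__(self, idx):
        a = self
        out = Tensor._make(a.data[idx], (a,), None)

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        out._backward = bwd if out.requires_grad else None
        return out

    @staticmethod
    def concat(tensors, axis: int = 0):
        tensors = [_wrap(t) for t in tensors]
        out = Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None
        )
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accum(piece)

        out._backward = bwd if out.requires_grad else None
        return out

    # -- convolution -------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias=None, stride=1, padding=0, groups: int = 1):
        """2-D cross-correlation, NCHW layout.

        ``weight`` is ``(C_out, C_in // groups, kh, kw)``; a 5-D weight
        ``(N, C_out, C_in // groups, kh, kw)`` applies a distinct kernel to
        every sample of the batch (the dynamic-convolution path).
        """
        return _conv2d(self, _wrap(weight), None if bias is None else _wrap(bias),
                       _pair(stride), _pair(padding), groups)

    def avg_pool2d(self, k: int):
        """Non-overlapping k×k average pooling (spatial dims divisible by k)."""
        a = self
        n, c, h, w = a.data.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool {k}")
        y = a.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
        out = Tensor._make(y, (a,), None)

        def bwd(g):
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            a._accum(gx)

        out._backward = bwd if out.requires_grad else None
        return out


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v), int(v))


def _conv2d(x: Tensor, w: Tensor, b, stride, padding, groups: int) -> Tensor:
    sh, sw = stride
    ph, pw = padding
    per_sample = w.data.ndim == 5
    n, cin, h, hw = x.data.shape
    if per_sample:
        _, cout, cin_g, kh, kw = w.data.shape
    else:
        cout, cin_g, kh, kw = w.data.shape
    if cin // groups != cin_g:
        raise ValueError(
            f"channel mismatch: input has {cin} channels but kernel expects "
            f"{cin_g * groups} (groups={groups})"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    # (N, C, Ho, Wo, kh, kw) view — no copy
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    g = groups
    cols_g = cols.reshape(n, g, cin_g, ho, wo, kh, kw)
    if per_sample:
        w_g = w.data.reshape(n, g, cout // g, cin_g, kh, kw)
        y = np.einsum("ngchwkl,ngockl->ngohw", cols_g, w_g, optimize=True)
    else:
        w_g = w.data.reshape(g, cout // g, cin_g, kh, kw)
        y = np.einsum("ngchwkl,gockl->ngohw", cols_g, w_g, optimize=True)
    y = y.reshape(n, cout, ho, wo)
    if b is not None:
        y = y + b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(y, parents, None)
    if not out.requires_grad:
        return out

    def bwd(gy):
        gy_g = gy.reshape(n, g, cout // g, ho, wo)
        if w.requires_grad:
            if per_sample:
                gw = np.einsum("ngchwkl,ngohw->ngockl", cols_g, gy_g, optimize=True)
                w._accum(gw.reshape(w.data.shape))
            else:
                gw = np.einsum("ngchwkl,ngohw->gockl", cols_g, gy_g, optimize=True)
                w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if per_sample:
                gcols = np.einsum("ngockl,ngohw->ngchwkl", w_g, gy_g, optimize=True)
            else:
                gcols = np.einsum("gockl,ngohw->ngchwkl", w_g, gy_g, optimize=True)
            gcols = gcols.reshape(n, cin, ho, wo, kh, kw)
            gxp = np.zeros((n, cin, hp, wp))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += gcols[..., i, j]
            x._accum(gxp[:, :, ph : hp - ph or None, pw : wp - pw or None])

    out._backward = bwd
    return out
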