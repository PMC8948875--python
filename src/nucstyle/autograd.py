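"""Minimal reverse-mode automatic differentiation over numpy arrays.

The style-transfer model needs only a small, fixed set of differentiable
operations (convolution, a few pointwise nonlinearities, reductions and
reshapes), so the engine is deliberately compact: a :class:`Tensor` wraps an
``ndarray`` and records a closure that propagates gradients to its parents.
Graphs are built eagerly and freed after ``backward``.

Layout convention for image tensors is NCHW throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample2x", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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

    def __init__(self, data, requires_grad: bool = False, dtype=np.float32):
        self.data = np.asarray(data, dtype=dtype)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
            # free the graph as we go
            t._backward = None
            t._parents = ()

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return self._make(self.data / other.data, (self, other), back)

    def __pow__(self, p: float):
        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), back)

    def matmul(self, other: "Tensor") -> "Tensor":
        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), back)

    __matmul__ = matmul

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), back)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), back)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def back(g):
            if self.requires_grad:
                self._accum(g * factor)

        return self._make(self.data * factor, (self,), back)

    def abs(self):
        sign = np.sign(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), back)

    def clamp(self, lo: float, hi: float):
        inside = (self.data > lo) & (self.data < hi)

        def back(g):
            if self.requires_grad:
                self._accum(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), back)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        orig = self.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), back)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), back)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis."""
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def back(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                buf[sl] = g
                self._accum(buf)

        return self._make(self.data[sl], (self,), back)

    def logsumexp(self, axis: int):
        """Numerically stable log-sum-exp along `axis` (keepdims)."""
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        return shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = back
    return out


# ---------------------------------------------------------------------------
# Convolution via im2col; col2im implemented as k*k vectorized shifted adds.
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # n, c, oh, ow, k, k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, c * k * k
    )
    return cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, square kernel."""
    n, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    assert cin == c, f"channel mismatch: input {c}, weight expects {cin}"
    cols, oh, ow = _im2col(x.data, k, stride, pad)  # n, L, c*k*k
    wmat = weight.data.reshape(cout, -1)
    out_data = cols @ wmat.T  # n, L, cout
    out_data += bias.data
    out_data = np.ascontiguousarray(out_data.transpose(0, 2, 1)).reshape(
        n, cout, oh, ow
    )

    def back(g):
        gm = np.ascontiguousarray(
            g.reshape(n, cout, oh * ow).transpose(0, 2, 1)
        )  # n, L, cout
        if bias.requires_grad:
            bias._accum(gm.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("nlo,nlc->oc", gm, cols, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = (gm @ wmat).reshape(n, oh, ow, c, k, k)
            hp, wp = h + 2 * pad, w + 2 * pad
            gx = np.zeros((n, c, hp, wp), dtype=g.dtype)
            gcols = gcols.transpose(0, 3, 1, 2, 4, 5)  # n, c, oh, ow, k, k
            for ki in range(k):
                for kj in range(k):
                    gx[:, :, ki : ki + stride * oh : stride,
                       kj : kj + stride * ow : stride] += gcols[:, :, :, :, ki, kj]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    out = Tensor(out_data)
    if _GRAD_ENABLED[-1] and (x.requires_grad or weight.requires_grad or bias.requires_grad):
        out.requires_grad = True
        out._parents = (x, weight, bias)
        out._backward = back
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def back(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            gx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accum(gx)

    out = Tensor(out_data)
    if _GRAD_ENABLED[-1] and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = back
    return out
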