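"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations needed by the dual encoder and the
contrastive objective: broadcasting arithmetic, matmul (2-D and batched),
elementwise nonlinearities, reductions, reshapes, stable (log-)softmax,
embedding lookup, row gathering and strided 2-D convolution. Gradients are
accumulated by topological traversal from a scalar loss.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "conv2d", "avg_pool", "embedding", "take_rows"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # ---- graph plumbing -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ---- basic ops ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._result(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._result(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._result(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.data.shape),
                       _unbroadcast(g * a.data, b.data.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.powf(-1.0)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._result(a.data @ b.data, (a, b), backward)

    def powf(self, p: float):
        a = self
        out = a.data ** p
        return Tensor._result(out, (a,), lambda g: (g * p * a.data ** (p - 1.0),))

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._result(out, (a,), lambda g: (g * out,))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._result(a.data * mask, (a,), lambda g: (g * mask,))

    def gelu(self):
        """tanh-approximation GELU (multiplication-only form; integer powers
        through np.power are slow)."""
        a = self
        c = 0.7978845608028654  # sqrt(2/pi), python float: no float64 upcast
        x = a.data
        x2 = x * x
        t = np.tanh(c * x * (1.0 + 0.044715 * x2))
        out = 0.5 * x * (1.0 + t)

        def backward(g):
            du = c * (1.0 + 0.134145 * x2)
            d = 0.5 * (1.0 + t) + 0.5 * x * ((1.0 - t * t) * du)
            return (g * d,)

        return Tensor._result(out, (a,), backward)

    def sum(self, axis=None, keepdims=False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._result(out, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._result(a.data.reshape(shape), (a,),
                              lambda g: (g.reshape(a.data.shape),))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._result(a.data.transpose(axes), (a,),
                              lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        a = self

        def backward(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            return (ga,)

        return Tensor._result(a.data[idx], (a,), backward)

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return Tensor._result(s, (a,), backward)

    def log_softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        s = np.exp(out)

        def backward(g):
            return (g - s * g.sum(axis=axis, keepdims=True),)

        return Tensor._result(out, (a,), backward)

    # convenience
    def item(self):
        return float(self.data)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `weight[ids]` with scatter-add backward.

    The scatter is a one-hot matmul: for the small vocabularies used here it
    is much faster than np.add.at."""
    ids = np.asarray(ids)

    def backward(g):
        flat = ids.ravel()
        onehot = np.zeros((flat.size, weight.data.shape[0]), dtype=g.dtype)
        onehot[np.arange(flat.size), flat] = 1.0
        gw = onehot.T @ g.reshape(flat.size, -1)
        return (gw.reshape(weight.data.shape).astype(weight.data.dtype),)

    return Tensor._result(weight.data[ids], (weight,), backward)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather x[i, idx[i]] for each batch row i; x is (B, L, ...)."""
    idx = np.asarray(idx)
    rows = np.arange(x.data.shape[0])

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[rows, idx] = g
        return (gx,)

    return Tensor._result(x.data[rows, idx], (x,), backward)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """x: (B, H, W, C) -> patches (B, Ho, Wo, k, k, C) as a view copy."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    B, H, W, C = x.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    sB, sH, sW, sC = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(B, Ho, Wo, k, k, C),
        strides=(sB, sH * stride, sW * stride, sH, sW, sC), writeable=False)
    return np.ascontiguousarray(view), Ho, Wo


def avg_pool(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling, NHWC."""
    B, H, W, C = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims ({H}, {W}) not divisible by {k}")
    out = x.data.reshape(B, H // k, k, W // k, k, C).mean(axis=(2, 4))

    def backward(g):
        gx = np.broadcast_to(g[:, :, None, :, None, :] * (1.0 / (k * k)),
                             (B, H // k, k, W // k, k, C))
        return (gx.reshape(B, H, W, C).astype(g.dtype),)

    return Tensor._result(out, (x,), backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NHWC layout; weight is (k, k, Cin, Cout)."""
    k = weight.data.shape[0]
    cols, Ho, Wo = _im2col(x.data, k, stride, pad)
    B = x.data.shape[0]
    cin = x.data.shape[-1]
    cout = weight.data.shape[-1]
    flat = cols.reshape(B * Ho * Wo, k * k * cin)
    wmat = weight.data.reshape(k * k * cin, cout)
    out = (flat @ wmat + bias.data).reshape(B, Ho, Wo, cout)

    def backward(g):
        gflat = g.reshape(B * Ho * Wo, cout)
        gw = (flat.T @ gflat).reshape(weight.data.shape)
        gb = gflat.sum(axis=0)
        if not x.requires_grad:  # skip the costly col2im for leaf images
            return (None, gw, gb)
        gcols = (gflat @ wmat.T).reshape(B, Ho, Wo, k, k, cin)
        H, W = x.data.shape[1], x.data.shape[2]
        gxp = np.zeros((B, H + 2 * pad, W + 2 * pad, cin), dtype=g.dtype)
        for ki in range(k):
            for kj in range(k):
                gxp[:, ki:ki + stride * Ho:stride, kj:kj + stride * Wo:stride, :] += gcols[:, :, :, ki, kj, :]
        gx = gxp[:, pad:pad + H, pad:pad + W, :] if pad else gxp
        return (gx, gw, gb)

    return Tensor._result(out, (x, weight, bias), backward)
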