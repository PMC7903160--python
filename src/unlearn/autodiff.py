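"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the harmonisation networks need: dense and
2-D convolutional layers, 2x2 max pooling, nearest-neighbour upsampling,
channel concatenation, elementwise arithmetic, ReLU, log/exp and a numerically
stable ``log_softmax``.  Gradients are accumulated by a topological-order
backward sweep.  All tests gradient-check these primitives against central
finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "log_softmax", "conv2d", "maxpool2d", "upsample2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _bw
        return out

    # -- elementwise nonlinearities -----------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bw
        return out

    # -- reductions / reshaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accum(g)

    out._backward = _bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = Tensor(shifted - logsumexp, _prev=(x,))

    def _bw():
        if x.requires_grad:
            softmax = np.exp(out.data)
            g = out.grad
            x._accum(g - softmax * g.sum(axis=axis, keepdims=True))

    out._backward = _bw
    return out


# ---------------------------------------------------------------------------
# Convolutional primitives (NCHW layout, stride 1, symmetric zero padding)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """Return (B, C*kh*kw, OH*OW) patch matrix for stride-1 convolution."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, h, w = xp.shape
    oh, ow = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (b, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2, s3)
    )
    return np.ascontiguousarray(cols).reshape(b, c * kh * kw, oh * ow), (oh, ow)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int, pad: int) -> np.ndarray:
    """Scatter-add (B, C*kh*kw, OH*OW) patch gradients back onto the input grid."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = hp - kh + 1, wp - kw + 1
    xg = np.zeros((b, c, hp, wp))
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i : i + oh, j : j + ow] += cols[:, :, i, j]
    if pad:
        xg = xg[:, :, pad:-pad, pad:-pad]
    return xg


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution; x (B,C,H,W), weight (O,C,kh,kw), bias (O,)."""
    o, c, kh, kw = weight.shape
    cols, (oh, ow) = _im2col(x.data, kh, kw, pad)
    w2 = weight.data.reshape(o, -1)
    out_data = np.matmul(w2[None], cols).reshape(x.shape[0], o, oh, ow)
    out_data += bias.data[None, :, None, None]
    out = Tensor(out_data, _prev=(x, weight, bias))

    def _bw():
        g = out.grad.reshape(x.shape[0], o, -1)  # (B,O,P)
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            # sum over batch of g_b @ cols_b.T
            gw = np.einsum("bop,bkp->ok", g, cols)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.matmul(w2.T[None], g)  # (B, C*kh*kw, P)
            x._accum(_col2im(gcols, x.shape, kh, kw, pad))

    out._backward = _bw
    return out


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    b, c, h, w = x.shape
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bw():
        if not x.requires_grad:
            return
        g = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
        g = g.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(g.reshape(b, c, h, w))

    out._backward = _bw
    return out


def upsample2d(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), _prev=(x,))
    b, c, h, w = x.shape

    def _bw():
        if x.requires_grad:
            g = out.grad.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accum(g)

    out._backward = _bw
    return out
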