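"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package (a residual U-Net and a multi-branch attention
classifier) are small enough to train on a CPU, so the engine favours
clarity over generality: float32 throughout, NCHW layout for images, and
only the primitives those architectures need.  Convolution and pooling are
implemented as fused primitives (im2col + matmul) rather than composed from
elementary ops, which keeps both the tape and the arithmetic short.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward(out):
            self._accumulate(_unbroadcast(out.grad, self.shape))
            other._accumulate(_unbroadcast(out.grad, other.shape))

        return self._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            self._accumulate(-out.grad)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(out):
            self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        return self._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other._pow_const(-1.0)

    def _pow_const(self, p: float):
        def backward(out):
            self._accumulate(out.grad * p * np.power(self.data, p - 1.0))

        return self._result(np.power(self.data, p), (self,), backward)

    def sqrt(self):
        return self._pow_const(0.5)

    def matmul(self, other: "Tensor"):
        """Batched matrix multiply (delegates batching rules to np.matmul)."""
        other = self._wrap(other)

        def backward(out):
            a, b, g = self.data, other.data, out.grad
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return self._result(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(out):
            self._accumulate(out.grad.reshape(old))

        return self._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))

        def backward(out):
            self._accumulate(out.grad.transpose(inverse))

        return self._result(self.data.transpose(axes), (self,), backward)

    @staticmethod
    def concatenate(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(out):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(idx)])

        data = np.concatenate([t.data for t in tensors], axis=axis)
        return Tensor._result(data, tuple(tensors), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(out):
            self._accumulate(out.grad * mask)

        return self._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(out):
            self._accumulate(out.grad * y * (1.0 - y))

        return self._result(y, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(out):
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        return self._result(y, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        logp = z - lse

        def backward(out):
            g = out.grad
            softmax = np.exp(logp)
            self._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

        return self._result(logp, (self,), backward)

    def log(self):
        def backward(out):
            self._accumulate(out.grad / np.maximum(self.data, 1e-12))

        return self._result(np.log(np.maximum(self.data, 1e-12)), (self,), backward)

    # -- fused image primitives (NCHW) ----------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int = 1):
        """Stride-1 2-D convolution; weight (F, C, KH, KW), bias (F,)."""
        x = self.data
        n, c, h, w = x.shape
        f, _, kh, kw = weight.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        oh, ow = h + 2 * padding - kh + 1, w + 2 * padding - kw + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # n,c,oh,ow,kh,kw
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
        wmat = weight.data.reshape(f, c * kh * kw)
        out = cols @ wmat.T + bias.data
        out = out.transpose(0, 2, 1).reshape(n, f, oh, ow)

        def backward(o):
            g = o.grad.reshape(n, f, oh * ow).transpose(0, 2, 1)  # n, oh*ow, f
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1)))
            if weight.requires_grad:
                gw = np.einsum("npf,npk->fk", g, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.shape))
            if self.requires_grad:
                gcols = (g @ wmat).reshape(n, oh, ow, c, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + oh, j:j + ow] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                self._accumulate(gxp)

        return self._result(out, (self, weight, bias), backward)

    def max_pool2d(self, size: int = 2):
        """Non-overlapping max pooling with window `size` x `size`."""
        n, c, h, w = self.shape
        if h % size or w % size:
            raise ValueError(f"pooling window {size} does not tile {h}x{w}")
        oh, ow = h // size, w // size
        blocks = self.data.reshape(n, c, oh, size, ow, size)
        out = blocks.max(axis=(3, 5))
        mask = blocks == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first maximum per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, size * size)
        first = flat.argmax(axis=-1)
        onehot = np.eye(size * size, dtype=np.float32)[first]
        mask = onehot.reshape(n, c, oh, ow, size, size).transpose(0, 1, 2, 4, 3, 5)

        def backward(o):
            g = o.grad[:, :, :, None, :, None] * mask
            self._accumulate(g.reshape(n, c, h, w))

        return self._result(out, (self,), backward)

    def upsample_nearest(self, factor: int = 2):
        n, c, h, w = self.shape
        out = self.data.repeat(factor, axis=2).repeat(factor, axis=3)

        def backward(o):
            g = o.grad.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            self._accumulate(g)

        return self._result(out, (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"
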