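"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its generative networks with this engine.  Design goals are
a small, auditable operation set (everything the windowed-transformer generator
and the convolutional discriminators need), float64 arithmetic for easy
verification against finite differences, and strictly explicit randomness.

Graphs are built eagerly; ``Tensor.backward`` runs a topological sweep and
accumulates gradients into ``.grad``.  There is no implicit broadcasting magic
beyond numpy's own rules: broadcast axes are summed out on the way back.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
__all__ = ["Tensor", "Parameter", "concat", "stack", "set_default_dtype",
           "get_default_dtype"]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)

# float32 keeps desk-scale training memory-bound ops fast; gradient checks
# switch to float64 for finite-difference accuracy
_default_dtype = np.float32


def set_default_dtype(dtype) -> None:
    global _default_dtype
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("only float32/float64 supported")
    _default_dtype = np.dtype(dtype).type


def get_default_dtype():
    return _default_dtype


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # gradient accumulator of the backward sweep currently in flight
    _grads_ctx: dict[int, np.ndarray] | None = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_default_dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    @classmethod
    def _from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep at many layers)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            topo.append(node)
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append(p)
        # Kahn-style ordering by dependency count
        order: dict[int, int] = {}

        def _depth(t: Tensor) -> int:
            key = id(t)
            if key in order:
                return order[key]
            d = 1 + max((_depth(p) for p in t._parents if p.requires_grad), default=0)
            order[key] = d
            return d

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 10000 + 10 * len(topo)))
        try:
            for t in topo:
                _depth(t)
        finally:
            sys.setrecursionlimit(old)
        topo.sort(key=lambda t: order[id(t)], reverse=True)

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        prev = Tensor._grads_ctx
        Tensor._grads_ctx = grads
        try:
            for node in topo:
                g = grads.pop(id(node), None)
                if g is None:
                    continue
                if node.requires_grad and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                if node._backward is not None:
                    node._backward(g)
        finally:
            Tensor._grads_ctx = prev

    def _send(self, parent: "Tensor", grad: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        grads = Tensor._grads_ctx
        assert grads is not None
        key = id(parent)
        if key in grads:
            grads[key] = grads[key] + grad
        else:
            grads[key] = grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g, self.shape))
            out._send(other, _unbroadcast(g, other.shape))

        out = Tensor._from_op(self.data + other.data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, -g)

        out = Tensor._from_op(-self.data, (self,), backward)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g * other.data, self.shape))
            out._send(other, _unbroadcast(g * self.data, other.shape))

        out = Tensor._from_op(self.data * other.data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            out._send(self, _unbroadcast(g / other.data, self.shape))
            out._send(other, _unbroadcast(-g * self.data / (other.data * other.data),
                                          other.shape))

        out = Tensor._from_op(self.data / other.data, (self, other), backward)
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * e * self.data ** (e - 1.0))

        out = Tensor._from_op(self.data ** e, (self,), backward)
        return out

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(g: np.ndarray) -> None:
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            out._send(self, _unbroadcast(ga, self.shape))
            out._send(other, _unbroadcast(gb, other.shape))

        out = Tensor._from_op(np.matmul(self.data, other.data), (self, other), backward)
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape

        def backward(g: np.ndarray) -> None:
            out._send(self, g.reshape(src))

        out = Tensor._from_op(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g: np.ndarray) -> None:
            out._send(self, np.transpose(g, inv))

        out = Tensor._from_op(np.transpose(self.data, axes), (self,), backward)
        return out

    def roll(self, shift: Sequence[int], axes: Sequence[int]) -> "Tensor":
        shift = tuple(shift)
        axes = tuple(axes)

        def backward(g: np.ndarray) -> None:
            out._send(self, np.roll(g, tuple(-s for s in shift), axes))

        out = Tensor._from_op(np.roll(self.data, shift, axes), (self,), backward)
        return out

    def pad(self, pad_width: Sequence[tuple[int, int]]) -> "Tensor":
        pw = tuple(tuple(p) for p in pad_width)
        slices = tuple(slice(a, s + a) for (a, _), s in zip(pw, self.shape))

        def backward(g: np.ndarray) -> None:
            out._send(self, g[slices])

        out = Tensor._from_op(np.pad(self.data, pw), (self,), backward)
        return out

    def select(self, axis: int, index: int) -> "Tensor":
        """Take one slice along ``axis`` (removing the axis)."""
        src_shape = self.shape

        def backward(g: np.ndarray) -> None:
            gx = np.zeros(src_shape, dtype=g.dtype)
            idx = [slice(None)] * len(src_shape)
            idx[axis] = index
            gx[tuple(idx)] = g
            out._send(self, gx)

        out = Tensor._from_op(np.take(self.data, index, axis=axis), (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        src = self.shape

        def backward(g: np.ndarray) -> None:
            if axis is None:
                out._send(self, np.broadcast_to(g, src).copy())
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            out._send(self, np.broadcast_to(g, src).copy())

        out = Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def abs(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, g * np.sign(self.data))

        out = Tensor._from_op(np.abs(self.data), (self,), backward)
        return out

    def exp(self) -> "Tensor":
        val = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * val)

        out = Tensor._from_op(val, (self,), backward)
        return out

    def log(self) -> "Tensor":
        def backward(g: np.ndarray) -> None:
            out._send(self, g / self.data)

        out = Tensor._from_op(np.log(self.data), (self,), backward)
        return out

    def sqrt(self) -> "Tensor":
        val = np.sqrt(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * 0.5 / val)

        out = Tensor._from_op(val, (self,), backward)
        return out

    def sigmoid(self) -> "Tensor":
        val = ndtr_free_sigmoid(self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * val * (1.0 - val))

        out = Tensor._from_op(val, (self,), backward)
        return out

    def softplus(self) -> "Tensor":
        # log(1 + e^x), numerically stable for both tails
        val = np.logaddexp(0.0, self.data)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * ndtr_free_sigmoid(self.data))

        out = Tensor._from_op(val, (self,), backward)
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g: np.ndarray) -> None:
            out._send(self, g * mask)

        out = Tensor._from_op(self.data * mask, (self,), backward)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g: np.ndarray) -> None:
            out._send(self, g * factor)

        out = Tensor._from_op(self.data * factor, (self,), backward)
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation (Hendrycks & Gimpel); derivative reuses the
        # stored tanh to keep the backward pass cheap
        x = self.data
        x2 = x * x
        u = _SQRT_2_OVER_PI * (x + 0.044715 * x2 * x)
        t = np.tanh(u)
        val = 0.5 * x * (1.0 + t)

        def backward(g: np.ndarray) -> None:
            du = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * x2)
            dval = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du
            out._send(self, g * dval)

        out = Tensor._from_op(val, (self,), backward)
        return out

    # -- fused ops ------------------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)

        def backward(g: np.ndarray) -> None:
            dot = (g * val).sum(axis=axis, keepdims=True)
            out._send(self, val * (g - dot))

        out = Tensor._from_op(val, (self,), backward)
        return out

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        """Normalize over the last axis to zero mean / unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = (self.data - mu) * inv

        def backward(g: np.ndarray) -> None:
            gm = g.mean(axis=-1, keepdims=True)
            gy = (g * y).mean(axis=-1, keepdims=True)
            out._send(self, (g - gm - y * gy) * inv)

        out = Tensor._from_op(y, (self,), backward)
        return out

    def conv(self, weight: "Tensor", bias: "Tensor", stride: int, padding: int) -> "Tensor":
        """N-dimensional strided convolution (cross-correlation).

        ``self``  : (B, *S, Cin); ``weight``: (*K, Cin, Cout); ``bias``: (Cout,).
        Spatial rank is inferred from the weight.  Zero padding is symmetric.
        """
        rank = weight.ndim - 2
        kshape = weight.shape[:rank]
        cin, cout = weight.shape[rank], weight.shape[rank + 1]
        if self.shape[-1] != cin:
            raise ValueError("channel mismatch in conv")
        pw = ((0, 0),) + ((padding, padding),) * rank + ((0, 0),)
        xp = np.pad(self.data, pw)
        axes = tuple(range(1, 1 + rank))
        win = sliding_window_view(xp, kshape, axis=axes)
        # win: (B, P1, ..., Pr, Cin, k1, ..., kr) -> subsample stride
        sub = (slice(None),) + (slice(None, None, stride),) * rank
        win = win[sub]
        out_spatial = win.shape[1:1 + rank]
        # move Cin behind kernel axes -> (B, O..., k..., Cin)
        win = np.moveaxis(win, 1 + rank, -1)
        wmat = weight.data.reshape(-1, cout)  # (k^r * Cin, Cout)
        wcol = win.reshape(win.shape[:1 + rank] + (-1,))
        val = wcol @ wmat + bias.data

        def backward(g: np.ndarray) -> None:
            gflat = g.reshape(-1, cout)
            colflat = wcol.reshape(-1, wcol.shape[-1])
            gw = (colflat.T @ gflat).reshape(weight.shape)
            out._send(weight, gw)
            out._send(bias, gflat.sum(axis=0))
            if self.requires_grad:
                gx = np.zeros_like(xp)
                wd = weight.data  # (*K, Cin, Cout)
                for kidx in np.ndindex(*kshape):
                    # output o maps to padded-input position k + stride*o
                    sl = (slice(None),) + tuple(
                        slice(k, k + stride * o, stride)
                        for k, o in zip(kidx, out_spatial)) + (slice(None),)
                    gx[sl] += g @ wd[kidx].T
                crop = (slice(None),) + tuple(
                    slice(padding, padding + s) for s in self.shape[1:1 + rank]
                ) + (slice(None),)
                out._send(self, gx[crop])

        out = Tensor._from_op(val, (self, weight, bias), backward)
        return out


def ndtr_free_sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            out._send(t, g[tuple(idx)])

    out = Tensor._from_op(np.concatenate([t.data for t in tensors], axis=axis),
                          tensors, backward)
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)

    def backward(g: np.ndarray) -> None:
        for i, t in enumerate(tensors):
            out._send(t, np.take(g, i, axis=axis))

    out = Tensor._from_op(np.stack([t.data for t in tensors], axis=axis),
                          tensors, backward)
    return out
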