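"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains three small convolutional networks (an eyelid-side
classifier, a VAE-GAN shape prior and a U-Net segmenter) on CPU at desk
scale.  This module provides the tensor type and the differentiable
operations those models need -- nothing more.  Arrays are float64 NCHW;
graphs are built eagerly and freed after ``backward``.

Gradient correctness is checked against central finite differences in the
test suite for every op defined here.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d", "upsample2x", "crop2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free intermediary graph references
        for node in topo:
            if node._backward is not None:
                node._parents = ()
                node._backward = None

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic --------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**exponent, _parents=(self,))

        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0
        scale = np.where(mask, 1.0, slope)
        out = Tensor(self.data * scale, _parents=(self,))
        out._backward = lambda g: self._accum(g * scale)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def clamp(self, lo: float, hi: float) -> "Tensor":
        """Clip values; gradient passes only through unclipped entries."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    # -- reductions & reshaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [
                self.data.shape[a % self.data.ndim]
                for a in (axis if isinstance(axis, tuple) else (axis,))
            ]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose2d(self) -> "Tensor":
        out = Tensor(self.data.T, _parents=(self,))
        out._backward = lambda g: self._accum(g.T)
        return out


# -- structural ops ---------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])

    out._backward = bwd
    return out


# -- convolution machinery ---------------------------------------------------


def _im2col_indices(C, H, W, kh, kw, stride, pad):
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    i0 = np.repeat(np.arange(kh), kw)
    i0 = np.tile(i0, C)
    i1 = stride * np.repeat(np.arange(Ho), Wo)
    j0 = np.tile(np.arange(kw), kh * C)
    j1 = stride * np.tile(np.arange(Wo), Ho)
    i = i0.reshape(-1, 1) + i1.reshape(1, -1)  # (C*kh*kw, Ho*Wo)
    j = j0.reshape(-1, 1) + j1.reshape(1, -1)
    k = np.repeat(np.arange(C), kh * kw).reshape(-1, 1)
    return (k, i, j), Ho, Wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), w (O,C,kh,kw), b (O,)."""
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    (k, i, j), Ho, Wo = _im2col_indices(C, H, W, kh, kw, stride, pad)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = xp[:, k, i, j]  # (N, C*kh*kw, Ho*Wo)
    wmat = w.data.reshape(O, -1)  # (O, C*kh*kw)
    out_data = np.matmul(wmat, cols).reshape(N, O, Ho, Wo)
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        gmat = g.reshape(N, O, -1)  # (N, O, Ho*Wo)
        w._accum(np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.data.shape))
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)  # (N, C*kh*kw, Ho*Wo)
            Hp, Wp = H + 2 * pad, W + 2 * pad
            # scatter-add via bincount (much faster than np.add.at)
            flat = (k * Hp * Wp + i * Wp + j).ravel()
            dxp = np.empty((N, C, Hp, Wp))
            size = C * Hp * Wp
            for nidx in range(N):
                dxp[nidx] = np.bincount(
                    flat, weights=dcols[nidx].ravel(), minlength=size
                ).reshape(C, Hp, Wp)
            x._accum(dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp)

    out._backward = bwd
    return out


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; spatial dims must divide by k."""
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by pool size {k}")
    r = x.data.reshape(N, C, H // k, k, W // k, k)
    out = Tensor(r.mean(axis=(3, 5)), _parents=(x,))

    def bwd(g):
        g4 = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accum(g4)

    out._backward = bwd
    return out


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Keep the top-left h x w spatial window of an NCHW tensor."""
    N, C, H, W = x.data.shape
    if h > H or w > W:
        raise ValueError(f"cannot crop ({H},{W}) to larger ({h},{w})")
    out = Tensor(x.data[:, :, :h, :w], _parents=(x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        gx[:, :, :h, :w] = g
        x._accum(gx)

    out._backward = bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(out_data, _parents=(x,))
    N, C, H, W = x.data.shape

    def bwd(g):
        x._accum(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out
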