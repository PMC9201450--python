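"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` replays the tape in reverse topological order and
accumulates gradients into every tensor created with ``requires_grad=True``.
Only the operations the package's networks need are provided (elementwise
arithmetic, matmul with batch broadcasting, reductions, softmax, 2-D grouped
convolution).  Shapes follow the NCHW convention for images.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "conv2d", "softmax", "concatenate", "shift2d"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        self.data = arr if arr.dtype.kind == "f" else arr.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = ()
        out._backward = None
        out.requires_grad = False
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, exponent: float):
        data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data**(exponent - 1))

        return Tensor._make(data, (self,), backward)

    # -- transcendental ----------------------------------------------------
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def gelu(self):
        # tanh approximation of the Gaussian-error linear unit
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        data = 0.5 * x * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                dt = (1.0 - t**2) * dinner
                self._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; the gradient passes through unclamped entries only."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions and reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor._make(data, (self,), backward)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = _as_tensor(other)
        data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        return Tensor._make(data, (self, other), backward)

    __matmul__ = matmul


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` with a fused backward."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            x._accumulate(data * (g - dot))

    return Tensor._make(data, (x,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(data, tuple(tensors), backward)


def shift2d(x: Tensor, dy: int, dx: int) -> Tensor:
    """Zero-filled spatial shift on NCHW input: out(p, q) = x(p+dy, q+dx)."""
    N, C, H, W = x.data.shape

    def place(src, dyy, dxx):
        out = np.zeros_like(src)
        ys, yd = (dyy, 0) if dyy >= 0 else (0, -dyy)
        xs, xd = (dxx, 0) if dxx >= 0 else (0, -dxx)
        h = H - abs(dyy)
        w = W - abs(dxx)
        if h > 0 and w > 0:
            out[:, :, yd:yd + h, xd:xd + w] = src[:, :, ys:ys + h, xs:xs + w]
        return out

    def backward(g):
        if x.requires_grad:
            x._accumulate(place(g, -dy, -dx))

    return Tensor._make(place(x.data, dy, dx), (x,), backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation on NCHW input.

    ``weight`` has shape (C_out, C_in/groups, k, k).  Implemented with a
    strided sliding-window view and per-group einsum contractions; the
    input gradient is scattered back with one slice-add per kernel tap.
    """
    N, C, H, W = x.data.shape
    Co, Cg, kh, kw = weight.data.shape
    if C % groups or Co % groups or Cg != C // groups:
        raise ValueError("channel counts incompatible with group count")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    g = groups
    wg = weight.data.reshape(g, Co // g, Cg, kh, kw)
    if kh == 1 and kw == 1:
        xs = xp[:, :, ::stride, ::stride][:, :, :Ho, :Wo]
        cols = xs.reshape(N, g, Cg, Ho, Wo)
        out = np.einsum("ngchw,goc->ngohw", cols, wg[..., 0, 0], optimize=True)
    else:
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]
        cols = win.reshape(N, g, Cg, Ho, Wo, kh, kw)
        out = np.einsum("ngchwkl,gockl->ngohw", cols, wg, optimize=True)
    out = np.ascontiguousarray(out.reshape(N, Co, Ho, Wo))
    if bias is not None:
        out = out + bias.data.reshape(1, Co, 1, 1)

    def backward(grad):
        go = grad.reshape(N, g, Co // g, Ho, Wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(grad.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            if kh == 1 and kw == 1:
                xs = xp[:, :, ::stride, ::stride][:, :, :Ho, :Wo]
                colsb = xs.reshape(N, g, Cg, Ho, Wo)
                gw = np.einsum("ngohw,ngchw->goc", go, colsb, optimize=True)
                weight._accumulate(gw.reshape(Co, Cg, 1, 1))
            else:
                win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
                win = win[:, :, ::stride, ::stride]
                colsb = win.reshape(N, g, Cg, Ho, Wo, kh, kw)
                gw = np.einsum("ngohw,ngchwkl->gockl", go, colsb, optimize=True)
                weight._accumulate(gw.reshape(Co, Cg, kh, kw))
        if x.requires_grad:
            dxp = np.zeros((N, C, Hp, Wp), dtype=grad.dtype)
            if kh == 1 and kw == 1:
                dcols = np.einsum("ngohw,goc->ngchw", go, wg[..., 0, 0], optimize=True)
                dxp[:, :, ::stride, ::stride][:, :, :Ho, :Wo] += dcols.reshape(N, C, Ho, Wo)
            else:
                dcols = np.einsum("ngohw,gockl->ngchwkl", go, wg, optimize=True)
                dcols = dcols.reshape(N, C, Ho, Wo, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + stride * Ho:stride,
                            j:j + stride * Wo:stride] += dcols[:, :, :, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:Hp - padding, padding:Wp - padding]
            x._accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)
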