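"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
``ndarray`` and records, for every operation, a closure that propagates the
upstream gradient to its parents.  It supports exactly the operations the
contrastive losses and the small convolutional encoder need (broadcasted
arithmetic, matmul, exp/log/cos/arccos, clipping, reductions, reshapes and
an im2col convolution).  Gradients are accumulated with ``+=`` after a
topological sort, so shared subexpressions are handled correctly.

Numerical conventions: ``clip`` passes the gradient through only strictly
inside the interval (the clamp boundaries are measure-zero and treated as
flat), and ``logsumexp``-style stability is built by callers from ``detach``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ---------------------------------------------------------------- basics
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

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = backward
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))
        out._backward = lambda g: self._accum(g * val) if self.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = (
            lambda g: self._accum(g / self.data) if self.requires_grad else None
        )
        return out

    def cos(self) -> "Tensor":
        out = Tensor(np.cos(self.data), parents=(self,))
        out._backward = (
            lambda g: self._accum(-g * np.sin(self.data))
            if self.requires_grad
            else None
        )
        return out

    def arccos(self) -> "Tensor":
        # caller is responsible for keeping data strictly inside (-1, 1)
        out = Tensor(np.arccos(self.data), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(-g / np.sqrt(1.0 - self.data ** 2))

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient flows only strictly inside [lo, hi]."""
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        out._backward = (
            lambda g: self._accum(g * inside) if self.requires_grad else None
        )
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = (
            lambda g: self._accum(g.reshape(self.shape))
            if self.requires_grad
            else None
        )
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = (
            lambda g: self._accum(g.transpose(inv)) if self.requires_grad else None
        )
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Row gather: out[k] = self[index[k]]."""
        index = np.asarray(index)
        out = Tensor(self.data[index], parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accum(acc)

        out._backward = backward
        return out

    # -------------------------------------------------------------- backward
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep tapes would blow the recursion limit
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ----------------------------------------------------------------- functions
def stack_rows(tensors: Iterable[Tensor]) -> Tensor:
    """Stack 1-D tensors into a matrix (used only in small oracles)."""
    ts = list(tensors)
    out = Tensor(np.stack([t.data for t in ts]), parents=tuple(ts))

    def backward(g: np.ndarray) -> None:
        for k, t in enumerate(ts):
            if t.requires_grad:
                t._accum(g[k])

    out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, stride 1, square kernel.

    Implemented via im2col + matmul; the backward pass scatters the gradient
    back with the col2im adjoint.
    """
    n, c_in, h, w_in = x.shape
    c_out, c_in2, k, k2 = w.shape
    if c_in != c_in2 or k != k2:
        raise ValueError("conv2d: incompatible shapes")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    h_out, w_out = h + 2 * padding - k + 1, w_in + 2 * padding - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (n, c_in, h_out, w_out, k, k) -> cols (n*h_out*w_out, c_in*k*k)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h_out * w_out, c_in * k * k)
    wmat = w.data.reshape(c_out, c_in * k * k)
    val = (cols @ wmat.T).reshape(n, h_out, w_out, c_out).transpose(0, 3, 1, 2)
    val = val + b.data.reshape(1, c_out, 1, 1)
    out = Tensor(val, parents=(x, w, b))

    def backward(g: np.ndarray) -> None:
        g_mat = g.transpose(0, 2, 3, 1).reshape(n * h_out * w_out, c_out)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum((g_mat.T @ cols).reshape(c_out, c_in, k, k))
        if x.requires_grad:
            g_cols = g_mat @ wmat  # (n*h_out*w_out, c_in*k*k)
            g_cols = g_cols.reshape(n, h_out, w_out, c_in, k, k)
            gx = np.zeros_like(xp)
            for di in range(k):  # k is tiny (3); loop over kernel taps
                for dj in range(k):
                    gx[:, :, di : di + h_out, dj : dj + w_out] += g_cols[
                        :, :, :, :, di, dj
                    ].transpose(0, 3, 1, 2)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)

    out._backward = backward
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (even spatial dims required)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def logsumexp_rows(s: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise log Σ_j mask[i,j] · exp(s[i,j]), numerically stabilised.

    ``mask`` is a constant 0/1 matrix; masked-out entries never contribute,
    regardless of their value.
    """
    m = np.where(mask, s.data, -np.inf).max(axis=1, keepdims=True)
    shifted = s - Tensor(m)
    summed = (shifted.exp() * Tensor(mask.astype(float))).sum(axis=1)
    return summed.log() + Tensor(m[:, 0])
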