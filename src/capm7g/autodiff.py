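"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the capsule network needs: broadcasting
arithmetic, matmul, 2-D convolution (rectangular kernels and strides),
relu/sigmoid/exp/sqrt, axis reductions, reshape/transpose and a numerically
stable softmax. Gradients are accumulated by topological-order backward
passes; correctness is pinned by central-finite-difference tests.

All data is float64. The engine is deliberately small: no graphs across
steps, no in-place ops, no device abstraction.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

ArrayLike = "np.ndarray | float | int"


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] = lambda: None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._prev:
                    if id(p) not in seen:
                        stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- constructors -----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        out._prev = tuple(p for p in parents if p.requires_grad)
        return out

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = _backward
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = self._make(self.data**p, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other))

        def _backward():
            a, b = self.data, other.data
            if self.requires_grad:
                ga = out.grad @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ out.grad
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = _backward
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------

    def relu(self) -> "Tensor":
        out = self._make(np.maximum(self.data, 0.0), (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = self._make(s, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = self._make(e, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        r = np.sqrt(self.data)
        out = self._make(r, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * 0.5 / r)

        out._backward = _backward
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = _backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = self._make(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out._backward = _backward
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- composite ops -----------------------------------------------------

    def softmax(self, axis: int) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def relu(x: Tensor) -> Tensor:
    return x.relu()


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor], stride) -> Tensor:
    """2-D cross-correlation of x (B, C, H, W) with weight (O, C, kh, kw).

    ``stride`` is an int or (sh, sw) pair; no padding (valid mode).
    """
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    B, C, H, W = x.shape
    O, C2, kh, kw = weight.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, weight {C2}")
    if H < kh or W < kw:
        raise ValueError(f"input {H}x{W} smaller than kernel {kh}x{kw}")
    cols = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    cols = cols[:, :, ::sh, ::sw]  # (B, C, Ho, Wo, kh, kw)
    out_data = np.einsum("bchwij,ocij->bohw", cols, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(out_data, parents)
    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def _backward():
        g = out.grad  # (B, O, Ho, Wo)
        if weight.requires_grad:
            gw = np.einsum("bchwij,bohw->ocij", cols, g, optimize=True)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            # scatter each kernel tap's contribution back to the input
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum(
                        "bohw,oc->bchw", g, weight.data[:, :, i, j], optimize=True
                    )
                    gx[:, :, i : i + Ho * sh : sh, j : j + Wo * sw : sw] += contrib
            x._accum(gx)

    out._backward = _backward
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Affine map x (..., in) @ weight (in, out) + bias (out,)."""
    return x.matmul(weight) + bias


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 0.001,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
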