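"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in :mod:`cellformer.model` is small and has a fixed set of
building blocks (affine maps, row-wise layer normalisation, row L2
normalisation, ReLU, elementwise arithmetic with broadcasting, matrix
products and a fused softmax cross-entropy).  This module provides exactly
those primitives on a dynamic tape, so the model code reads like plain
NumPy while gradients come for free.  Gradients of every primitive are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "matmul",
    "relu",
    "layer_norm",
    "l2_normalize_rows",
    "concat_cols",
    "sum_all",
    "softmax_cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)
        out = _node(self.data + other.data, (self, other))

        def bwd():
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda: self._accumulate(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = _node(self.data * other.data, (self, other))

        def bwd():
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = _node(self.data / other.data, (self, other))

        def bwd():
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad or other._parents:
                other._accumulate(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        out = _node(self.data.T, (self,))
        out._backward = lambda: self._accumulate(out.grad.T)
        return out

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = parents
    return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = _node(a.data @ b.data, (a, b))

    def bwd():
        if a.requires_grad or a._parents:
            a._accumulate(out.grad @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ out.grad)

    out._backward = bwd
    return out


def relu(x) -> Tensor:
    x = astensor(x)
    out = _node(np.maximum(x.data, 0.0), (x,))
    out._backward = lambda: x._accumulate(out.grad * (x.data > 0.0))
    return out


def layer_norm(x, gamma, beta, eps: float = 1e-8) -> Tensor:
    """Row-wise layer normalisation with learnable scale and shift."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = _node(xhat * gamma.data + beta.data, (x, gamma, beta))

    def bwd():
        d = x.data.shape[-1]
        gy = out.grad * gamma.data
        if x.requires_grad or x._parents:
            # standard layer-norm backward: project out mean and xhat components
            gx = inv * (
                gy
                - gy.mean(axis=-1, keepdims=True)
                - xhat * (gy * xhat).mean(axis=-1, keepdims=True)
            )
            x._accumulate(gx)
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate(_unbroadcast(out.grad * xhat, gamma.shape))
        if beta.requires_grad or beta._parents:
            beta._accumulate(_unbroadcast(out.grad, beta.shape))

    out._backward = bwd
    return out


def l2_normalize_rows(x, eps: float = 1e-8) -> Tensor:
    """Scale each row of ``x`` to unit Euclidean norm."""
    x = astensor(x)
    norm = np.sqrt((x.data**2).sum(axis=-1, keepdims=True) + eps)
    y = x.data / norm
    out = _node(y, (x,))

    def bwd():
        g = out.grad
        # d/dx (x/||x||) = (I - y y^T)/||x||
        proj = (g * y).sum(axis=-1, keepdims=True)
        x._accumulate((g - y * proj) / norm)

    out._backward = bwd
    return out


def concat_cols(parts: Sequence[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along columns."""
    parts = [astensor(p) for p in parts]
    out = _node(np.concatenate([p.data for p in parts], axis=1), tuple(parts))
    widths = [p.data.shape[1] for p in parts]

    def bwd():
        off = 0
        for p, w in zip(parts, widths):
            if p.requires_grad or p._parents:
                p._accumulate(out.grad[:, off : off + w])
            off += w

    out._backward = bwd
    return out


def sum_all(x) -> Tensor:
    return astensor(x).sum()


def softmax_cross_entropy(logits, codes: np.ndarray) -> Tensor:
    """Mean cross-entropy between row-softmaxed ``logits`` and integer ``codes``."""
    logits = astensor(logits)
    codes = np.asarray(codes, dtype=np.int64)
    n = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    loss = -logp[np.arange(n), codes].mean()
    out = _node(np.array(loss), (logits,))

    def bwd():
        p = np.exp(logp)
        p[np.arange(n), codes] -= 1.0
        logits._accumulate(out.grad * p / n)

    out._backward = bwd
    return out
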