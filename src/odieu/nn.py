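"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's two training loops need:
the contrastive fine-tuning of linear sentence embedders and the prefix
encoder trained through a frozen causal language model.  Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self.grad += -g

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2, other.data.shape)

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out_data**2)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * out_data

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self.grad += g * 0.5 / np.maximum(out_data, 1e-300)

        return self._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g * np.sign(self.data)

        return self._make(np.abs(self.data), (self,), backward)

    def relu(self):
        def backward(g):
            if self.requires_grad:
                self.grad += g * (self.data > 0)

        return self._make(np.maximum(self.data, 0.0), (self,), backward)

    # -- reductions / shape ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if self.requires_grad:
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        return self._make(self.data.reshape(*shape), (self,), backward)

    def slice_cols(self, start: int, stop: int):
        def backward(g):
            if self.requires_grad:
                self.grad[..., start:stop] += g

        return self._make(self.data[..., start:stop], (self,), backward)

    def gather_rows(self, row_idx, col_idx):
        """out[i] = self[row_idx[i], col_idx[i]] (for cross-entropy)."""
        row_idx = np.asarray(row_idx)
        col_idx = np.asarray(col_idx)

        def backward(g):
            if self.requires_grad:
                np.add.at(self.grad, (row_idx, col_idx), g)

        return self._make(self.data[row_idx, col_idx], (self,), backward)


def concat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=0),
                 requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        offsets = np.cumsum([0] + [d.shape[0] for d in datas])

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    t.grad += g[a:b]

        out._parents = tuple(tensors)
        out._backward = backward
    return out


def logsumexp_rows(x: Tensor) -> Tensor:
    """Row-wise log-sum-exp of a 2-D tensor, max-shifted for stability."""
    shift = x.data.max(axis=1, keepdims=True)  # constant w.r.t. the graph
    return (x - shift).exp().sum(axis=1, keepdims=True).log() + shift


def l2_normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=1, keepdims=True) + eps).sqrt()
    return x / norm


class SGD:
    """Plain gradient descent (no momentum); monotone on smooth objectives
    at a small enough step."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
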