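"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the package's numerical engine: a small tape-based autodiff
supporting exactly the operations the synergy model, the listwise losses
and integrated gradients need (broadcast arithmetic, matmul against a 2-D
weight, gather/scatter for embeddings and convolution windows, axis
reductions, elementwise transcendentals). Everything runs in float64 on
CPU, so repeated runs with a fixed seed agree bitwise.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "Dense",
    "Embedding",
    "Conv1D",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self.grad: np.ndarray | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------
    def _node(self, data, parents, backward) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, parents=parents, backward=backward)
        return Tensor(data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._node(out_data, (self, other), backward)

    def __matmul__(self, other):
        """Matrix product; the right operand must be 2-D (a weight)."""
        other = as_tensor(other)
        if other.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out_data = self.data @ other.data

        def backward(g):
            k = self.shape[-1]
            a2 = self.data.reshape(-1, k)
            g2 = g.reshape(-1, g.shape[-1])
            return (
                (g2 @ other.data.T).reshape(self.shape),
                a2.T @ g2,
            )

        return self._node(out_data, (self, other), backward)

    # -- elementwise ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            return (g / self.data,)

        return self._node(np.log(self.data), (self,), backward)

    def log1p(self):
        def backward(g):
            return (g / (1.0 + self.data),)

        return self._node(np.log1p(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data**2),)

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._node(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            return (g * sign,)

        return self._node(np.abs(self.data), (self,), backward)

    # -- reductions / shape ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int):
        """Max over one axis; gradient flows to the first arg-max entry."""
        am = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(am, axis), axis).squeeze(axis)

        def backward(g):
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(am, axis), np.expand_dims(g, axis), axis)
            return (gx,)

        return self._node(out_data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            return (g.reshape(self.shape),)

        return self._node(self.data.reshape(shape), (self,), backward)

    def take(self, indices: np.ndarray, axis: int = 0):
        """Gather along `axis` (0 or 1) with an integer index array."""
        indices = np.asarray(indices)
        out_data = np.take(self.data, indices, axis=axis)

        def backward(g):
            gx = np.zeros_like(self.data)
            if axis == 0:
                np.add.at(gx, indices, g)
            elif axis == 1:
                np.add.at(gx, (slice(None), indices), g)
            else:  # pragma: no cover - not used
                raise ValueError("take supports axis 0 or 1")
            return (gx,)

        return self._node(out_data, (self,), backward)

    def slice_rows(self, start: int, stop: int):
        """Contiguous row slice; cheaper than take() for range indices."""

        def backward(g):
            gx = np.zeros_like(self.data)
            gx[start:stop] = g
            return (gx,)

        return self._node(self.data[start:stop], (self,), backward)

    # -- backprop --------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
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

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg
            if node._parents == () or node.grad is not None:
                node.grad = g if node.grad is None else node.grad + g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    if any(t.requires_grad for t in tensors):
        return Tensor(out_data, parents=tuple(tensors), backward=backward)
    return Tensor(out_data)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Dense:
    """Affine layer y = x @ W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class Embedding:
    """Token-index lookup table; index 0 doubles as pad / null-drug slot."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.1, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.W.take(np.asarray(idx, dtype=np.intp), axis=0)

    def parameters(self) -> list[Tensor]:
        return [self.W]


class Conv1D:
    """1-D convolution over (batch, length, channels), valid padding."""

    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        limit = np.sqrt(6.0 / (kernel * n_in + n_out))
        self.W = Tensor(
            rng.uniform(-limit, limit, size=(kernel * n_in, n_out)), requires_grad=True
        )
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        length = x.shape[1]
        n_out = length - self.kernel + 1
        if n_out < 1:
            raise ValueError(f"sequence length {length} shorter than kernel {self.kernel}")
        win = np.arange(self.kernel)[None, :] + np.arange(n_out)[:, None]
        cols = x.take(win, axis=1)  # (B, n_out, kernel, C)
        cols = cols.reshape(x.shape[0], n_out, self.kernel * x.shape[2])
        return cols @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 / (1 - self.b1**self.t)
        c2 = 1.0 / (1 - self.b2**self.t)
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v = self._m[i], self._v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m * c1) / (np.sqrt(v * c2) + self.eps)
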