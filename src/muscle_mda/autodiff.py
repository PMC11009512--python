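"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the graph-attention encoder, the fusion
module and the MLP classifier need: broadcasting arithmetic, matmul,
reductions, gathers/concatenation and the activation functions.  Gradients
accumulate in float64; the engine is single-threaded and eager, with a
topological-sort backward pass.

This is deliberately a micro-engine, not a framework: no graphs spanning
sessions, no in-place ops, no dtype promotion games.  Tests verify every
primitive against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: Tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph holding a float64 array and its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Optional[Array] = None) -> None:
        """Backpropagate from this node; defaults to d(self)/d(self) = 1."""
        order: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data ** exponent, parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g: Array) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                grad = np.broadcast_to(g, self.shape).copy()
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                gg = g
                if not keepdims:
                    for ax in sorted(a % self.data.ndim for a in axes):
                        gg = np.expand_dims(gg, ax)
                grad = np.broadcast_to(gg, self.shape).copy()
            self._accumulate(grad)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = bwd
        return out

    def transpose(self, *axes: int) -> "Tensor":
        perm = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(perm)
        out = Tensor(self.data.transpose(perm), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def gather_rows(self, idx: Sequence[int]) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx, g)
                self._accumulate(grad)

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = bwd
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        val = np.where(pos, self.data, alpha * np.expm1(self.data))
        out = Tensor(val, parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, val + alpha))

        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        s = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, None, 500))),
            np.exp(np.clip(self.data, -500, None))
            / (1.0 + np.exp(np.clip(self.data, -500, None))),
        )
        out = Tensor(s, parents=(self,))

        def bwd(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis (differentiable)."""
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bwd(g: Array) -> None:
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, k, axis=axis))

    out._backward = bwd
    return out


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    """Wrap an array (or draw Glorot-style init) as a trainable tensor."""
    return Tensor(data, requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, *shape: int) -> Tensor:
    """Glorot-uniform initialized trainable tensor of the given shape."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)),
                  requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of trainable tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
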