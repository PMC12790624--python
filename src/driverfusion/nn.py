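"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package (per-view graph convolutions, attention fusion,
gene-set attention, a transformer encoder with an additive attention bias,
focal loss, AdamW) is small enough that a dense/sparse numpy implementation
is fast at the graph sizes we train on. This module provides the vectorised
tape: a :class:`Tensor` wrapping a float64 ndarray, a closed set of
differentiable primitives, and an :class:`AdamW` optimizer. Gradients of
every primitive are validated against central finite differences in the
test suite.

Only the operations the model needs are implemented; this is not a general
deep-learning framework.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import erf

__all__ = [
    "Tensor",
    "Sparse",
    "add",
    "sub",
    "neg",
    "mul",
    "matmul",
    "transpose",
    "relu",
    "gelu",
    "sigmoid",
    "log",
    "exp",
    "power",
    "clip",
    "sum_",
    "mean_",
    "softmax",
    "concat",
    "take_rows",
    "slice_cols",
    "dropout",
    "spmm",
    "index_add_rows",
    "scatter_pairs",
    "layer_norm",
    "AdamW",
    "uniform_fan_in",
    "zeros_param",
]


class Tensor:
    """A node in the computation graph.

    ``_backward(grad)`` returns one gradient array per parent, aligned with
    ``_parents``. Leaves created with ``requires_grad=True`` accumulate into
    ``.grad`` when :meth:`backward` is called on a downstream scalar.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                order.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
        # flush any leaves that were assigned directly
        for key, g in grads.items():  # pragma: no cover - defensive
            raise RuntimeError("unconsumed gradient in backward pass")

    # light operator sugar for readability in model code
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return neg(self)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


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


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return Tensor(-a.data, parents=(a,), backward=lambda g: (-g,))


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward=lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        backward=lambda g: (g @ b.data.T, a.data.T @ g),
    )


def transpose(a) -> Tensor:
    a = _as_tensor(a)
    return Tensor(a.data.T, parents=(a,), backward=lambda g: (g.T,))


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = _as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    out = x * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        return (g * (cdf + x * pdf),)

    return Tensor(out, parents=(a,), backward=backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ez = np.exp(a.data[~pos])
    out[~pos] = ez / (1.0 + ez)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out * (1.0 - out),))


def log(a) -> Tensor:
    a = _as_tensor(a)
    return Tensor(np.log(a.data), parents=(a,), backward=lambda g: (g / a.data,))


def exp(a) -> Tensor:
    a = _as_tensor(a)
    out = np.exp(a.data)
    return Tensor(out, parents=(a,), backward=lambda g: (g * out,))


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    out = np.power(a.data, p)
    return Tensor(
        out, parents=(a,), backward=lambda g: (g * p * np.power(a.data, p - 1.0),)
    )


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where the input lies inside [lo, hi]."""
    a = _as_tensor(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)
    return Tensor(out, parents=(a,), backward=lambda g: (g * mask,))


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return Tensor(out, parents=(a,), backward=backward)


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return Tensor(out, parents=(a,), backward=backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, parents=tuple(tensors), backward=backward)


def take_rows(a, idx: np.ndarray) -> Tensor:
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(a.data[idx], parents=(a,), backward=backward)


def slice_cols(a, start: int, stop: int) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        out = np.zeros_like(a.data)
        out[:, start:stop] = g
        return (out,)

    return Tensor(a.data[:, start:stop], parents=(a,), backward=backward)


def dropout(a, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity in eval mode or at rate 0."""
    a = _as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep) / keep
    return mul(a, Tensor(mask))


class Sparse:
    """A constant sparse matrix (CSR) with its transpose cached for backprop."""

    def __init__(self, mat: sp.spmatrix):
        self.mat = sp.csr_matrix(mat)
        self.mat_t = sp.csr_matrix(self.mat.T)

    @property
    def shape(self):
        return self.mat.shape


def spmm(A: Sparse, x) -> Tensor:
    """Sparse-constant @ dense-tensor product."""
    x = _as_tensor(x)
    return Tensor(A.mat @ x.data, parents=(x,), backward=lambda g: (A.mat_t @ g,))


def index_add_rows(values, ids: np.ndarray, n_rows: int) -> Tensor:
    """Scatter-add rows of ``values`` (E, C) into an (n_rows, C) output by ``ids``."""
    values = _as_tensor(values)
    ids = np.asarray(ids, dtype=np.intp)
    out = np.zeros((n_rows,) + values.data.shape[1:], dtype=np.float64)
    np.add.at(out, ids, values.data)
    return Tensor(out, parents=(values,), backward=lambda g: (g[ids],))


def scatter_pairs(values, rows: np.ndarray, cols: np.ndarray, n: int) -> Tensor:
    """Place per-pair values symmetrically into a dense (n, n) matrix.

    ``rows[k] < cols[k]`` must hold (canonical undirected pairs); entries not
    covered by any pair stay exactly zero.
    """
    values = _as_tensor(values)
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    out = np.zeros((n, n), dtype=np.float64)
    out[rows, cols] = values.data
    out[cols, rows] = values.data
    return Tensor(
        out, parents=(values,), backward=lambda g: (g[rows, cols] + g[cols, rows],)
    )


def layer_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalization with learnable gain/offset."""
    mu = mean_(x, axis=1, keepdims=True)
    xc = sub(x, mu)
    var = mean_(mul(xc, xc), axis=1, keepdims=True)
    inv = power(add(var, Tensor(eps)), -0.5)
    return add(mul(mul(xc, inv), gamma), beta)


def uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    t = Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)
    return t


def zeros_param(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class AdamW:
    """AdamW with decoupled weight decay.

    ``no_decay`` marks parameters (biases, layer-norm gains/offsets) exempt
    from decay, following standard practice.
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float,
        weight_decay: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        no_decay: Iterable[Tensor] = (),
    ):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self._no_decay = {id(p) for p in no_decay}
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and id(p) not in self._no_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update
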