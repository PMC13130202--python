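"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the models in this package: dense float64
tensors, a handful of elementwise and matrix operations, broadcasting on
add/mul, and an Adam optimizer.  Gradients are accumulated by a reverse
topological sweep from a scalar loss.  Correctness is checked against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this scalar; fills ``.grad`` on ancestors."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    order.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self.grad += -g

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        if other.data.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")

        def bw(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                a = self.data.reshape(-1, self.data.shape[-1])
                other.grad += a.T @ g.reshape(-1, g.shape[-1])

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    @property
    def T(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g.T

        return Tensor(self.data.T, parents=(self,), backward=bw)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        def bw(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def rows(self, start: int, stop: int):
        """Contiguous row slice [start:stop)."""

        def bw(g):
            if self.requires_grad:
                self.grad[start:stop] += g

        return Tensor(self.data[start:stop], parents=(self,), backward=bw)

    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if self.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self.grad += g * mask

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            if self.requires_grad:
                self.grad += g * factor

        return Tensor(self.data * factor, parents=(self,), backward=bw)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expm1 = alpha * np.expm1(np.minimum(self.data, 0.0))
        out = np.where(pos, self.data, expm1)

        def bw(g):
            if self.requires_grad:
                self.grad += g * np.where(pos, 1.0, expm1 + alpha)

        return Tensor(out, parents=(self,), backward=bw)

    def sigmoid(self):
        out = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def bw(g):
            if self.requires_grad:
                self.grad += g * out * (1.0 - out)

        return Tensor(out, parents=(self,), backward=bw)

    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self.grad += g * out

        return Tensor(out, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self.grad += g / self.data

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def softplus(self):
        """log(1 + e^x), computed stably; derivative is the logistic."""
        out = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bw(g):
            if self.requires_grad:
                self.grad += g * sig

        return Tensor(out, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_cols(tensors) -> Tensor:
    """Concatenate 2-D tensors along axis 1."""
    tensors = [as_tensor(t) for t in tensors]
    widths = [t.data.shape[1] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(widths)])

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.grad += g[:, a:b]

    return Tensor(np.concatenate([t.data for t in tensors], axis=1),
                  parents=tuple(tensors), backward=bw)


def pad_rows(t: Tensor, n_below: int) -> Tensor:
    """Append ``n_below`` zero rows below a 2-D tensor."""
    t = as_tensor(t)
    r = t.data.shape[0]

    def bw(g):
        if t.requires_grad:
            t.grad += g[:r]

    out = np.concatenate(
        [t.data, np.zeros((n_below, t.data.shape[1]))], axis=0
    )
    return Tensor(out, parents=(t,), backward=bw)


def repeat_rows(t: Tensor, k: int) -> Tensor:
    """Repeat each row k times consecutively: rows (0,0,..,1,1,..)."""
    t = as_tensor(t)
    r = t.data.shape[0]

    def bw(g):
        if t.requires_grad:
            t.grad += g.reshape(r, k, -1).sum(axis=1)

    return Tensor(np.repeat(t.data, k, axis=0), parents=(t,), backward=bw)


def tile_rows(t: Tensor, k: int) -> Tensor:
    """Stack k copies of the whole matrix: rows (0..r-1, 0..r-1, ...)."""
    t = as_tensor(t)
    r = t.data.shape[0]

    def bw(g):
        if t.requires_grad:
            t.grad += g.reshape(k, r, -1).sum(axis=0)

    return Tensor(np.tile(t.data, (k, 1)), parents=(t,), backward=bw)


def masked_softmax_rows(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean, same shape).

    Masked-out positions get probability 0; every row must have at least
    one admitted position.  The row max is subtracted as a constant for
    stability (the softmax value and gradient are unchanged by this shift).
    """
    if not mask.any(axis=1).all():
        raise ValueError("masked_softmax_rows: some row has an empty mask")
    m = Tensor(mask.astype(np.float64))
    shift = np.where(mask, logits.data, -np.inf).max(axis=1, keepdims=True)
    # zero out excluded positions BEFORE exp so they cannot overflow
    e = ((logits - Tensor(shift)) * m).exp() * m
    return e / e.sum(axis=1, keepdims=True)


def dropout(t: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout with a fixed rng draw; identity when rate == 0."""
    if rate <= 0.0:
        return t
    keep = (rng.random(t.data.shape) >= rate) / (1.0 - rate)
    return t * Tensor(keep)


class Adam:
    """Standard Adam over a list of parameter Tensors (full-batch use)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data  # decoupled

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
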