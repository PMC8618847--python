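"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for the frame classifiers: dense layers,
valid-padding 2-D convolutions expressed as shifted matrix products, gated
recurrent units, dropout, and a numerically stable binary cross-entropy on
logits, together with the Adam optimizer. The engine is deliberately tiny —
only the operations the two architectures need — and fully deterministic
given a seeded ``numpy.random.Generator``.

Gradients are accumulated by iterative topological traversal, so long
recurrent chains (hundreds of timesteps) do not touch the Python recursion
limit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


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
    """A NumPy array plus the closure that routes its gradient to parents."""

    __slots__ = ("data", "grad", "_parents", "_bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            return g @ other.data.T, self.data.T @ g

        out._bwd = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bwd(g):
            gp = np.zeros_like(self.data)
            np.add.at(gp, idx, g)
            return (gp,)

        out._bwd = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._bwd = lambda g: (g.reshape(self.data.shape),)
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._bwd = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        s = _sigmoid(self.data)
        out = Tensor(s, (self,))
        out._bwd = lambda g: (g * s * (1.0 - s),)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, (self,))
        out._bwd = lambda g: (g * (1.0 - t * t),)
        return out

    # ---- backward pass ----------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological order (graphs from RNN loops are deep)
        order: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._bwd is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._bwd(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._bwd = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack_time(tensors) -> Tensor:
    """Stack per-timestep (B, F) tensors into (B, T, F)."""
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=1), tensors)
    out._bwd = lambda g: tuple(g[:, t] for t in range(len(tensors)))
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed directly on logits.

    loss = mean(max(z, 0) - z*y + log(1 + exp(-|z|))); the gradient is the
    classic (sigmoid(z) - y) / n, both stable for large |z|.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    out = Tensor(loss, (logits,))
    n = z.size
    out._bwd = lambda g: (g * (_sigmoid(z) - y) / n,)
    return out


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    n = max(rows, cols)
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols]


class Adam:
    """Adam with the conventional defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * p.grad
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * p.grad**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
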