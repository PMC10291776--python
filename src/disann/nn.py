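"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the character language model and the
BiLSTM-CRF tagger: a tape-based scalar/tensor autodiff with exactly the
operations those models need (affine maps, gate nonlinearities, slicing and
concatenation, log-sum-exp, gathers) plus an LSTM cell and an Adam optimizer.
All computation is float64 and single-threaded, so a fixed seed gives
bit-reproducible training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "LSTM", "Adam", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # -- graph construction helpers -------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        return Tensor(data, parents=parents, backward=backward)

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def tanh(self):
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def sum(self):
        out = self.data.sum()

        def backward(g):
            return (np.full_like(self.data, float(g)),)

        return self._make(out, (self,), backward)

    def gather(self, rows: np.ndarray, cols: np.ndarray):
        """Select ``data[rows[i], cols[i]]`` for each i, returning a vector."""
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        out = self.data[rows, cols]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, cols), g)
            return (full,)

        return self._make(out, (self,), backward)

    def take_rows(self, idx: np.ndarray):
        """Row gather ``data[idx]`` with scatter-add gradient (embedding lookup)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out, (self,), backward)

    # -- backprop --------------------------------------------------------
    def backward(self):
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor(out_data, tuple(tensors), backward)


def logsumexp(t: Tensor, axis: int) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    exp = np.exp(t.data - m)
    s = exp.sum(axis=axis, keepdims=True)
    out = np.squeeze(m + np.log(s), axis=axis)
    soft = exp / s

    def backward(g):
        return (np.expand_dims(g, axis) * soft,)

    return Tensor(out, (t,), backward)


class LSTM:
    """Single-layer LSTM over one sequence (no batching).

    Weights follow the fused-gate layout ``[x_t, h_{t-1}] @ W + b`` with gate
    order input, forget, cell, output.  The forget-gate bias starts at 1, a
    standard initialization that eases gradient flow early in training.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        scale = 1.0 / np.sqrt(input_dim + hidden_dim)
        self.W = Parameter(rng.uniform(-scale, scale, size=(input_dim + hidden_dim, 4 * hidden_dim)))
        b = np.zeros(4 * hidden_dim)
        b[hidden_dim : 2 * hidden_dim] = 1.0
        self.b = Parameter(b)

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden_dim
        z = concat([x_t, h], axis=1) @ self.W + self.b
        i = z[:, 0:H].sigmoid()
        f = z[:, H : 2 * H].sigmoid()
        g = z[:, 2 * H : 3 * H].tanh()
        o = z[:, 3 * H : 4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def run(self, inputs: Tensor, reverse: bool = False,
            h0: Tensor | None = None, c0: Tensor | None = None) -> Tensor:
        """Run over an (n, input_dim) sequence; returns (n, hidden_dim) states.

        Output row i is the hidden state *after* consuming input i, in the
        original sequence order even when ``reverse`` is set.
        """
        n = inputs.data.shape[0]
        h = h0 if h0 is not None else Tensor(np.zeros((1, self.hidden_dim)))
        c = c0 if c0 is not None else Tensor(np.zeros((1, self.hidden_dim)))
        order = range(n - 1, -1, -1) if reverse else range(n)
        outs: list[Tensor | None] = [None] * n
        for t in order:
            h, c = self.step(inputs[t : t + 1, :], h, c)
            outs[t] = h
        return concat([o for o in outs], axis=0)


class Adam:
    """Adam optimizer with global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
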