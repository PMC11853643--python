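"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model components in this package (multi-head attention encoder, graph
propagation layers, dual-stream predictor) are small enough that a compact
tape-based engine over dense ``float64`` arrays is both fast and exactly
reproducible on CPU.  Only the operations those models need are provided:
broadcasting arithmetic, (batched) matmul, pointwise nonlinearities, softmax,
reductions, indexing/gather, concatenation, and segment operations for
variable-size graph neighborhoods.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order.  Correctness is
checked against central finite differences in the test-suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "segment_sum",
    "segment_mean",
    "segment_max",
    "segment_softmax",
    "softmax",
    "layer_norm",
    "dropout",
    "xavier_uniform",
    "Adam",
    "ReduceLROnPlateau",
]


def _scatter_add(target: np.ndarray, indices: np.ndarray,
                 values: np.ndarray) -> None:
    """``target[indices] += values`` with repeated indices (sort + reduceat;
    much faster than ``np.add.at`` for large index arrays)."""
    if indices.size == 0:
        return
    order = np.argsort(indices, kind="stable")
    sorted_idx = indices[order]
    sorted_vals = values[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(sorted_idx)) + 1))
    sums = np.add.reduceat(sorted_vals, starts, axis=0)
    target[sorted_idx[starts]] += sums


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data: np.ndarray, parents: Sequence["Tensor"],
                 backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        # accumulate out-of-place: stored gradients are never mutated, so the
        # first contribution may be kept by reference
        self.grad = grad if self.grad is None else self.grad + grad

    # -- basic introspection ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ------------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(grad):
            self._accum(grad)
            other._accum(grad)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            self._accum(-grad)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(grad):
            if self.requires_grad:
                self._accum(grad * other.data)
            if other.requires_grad:
                other._accum(grad * self.data)

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(grad):
            self._accum(grad * exponent * self.data ** (exponent - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(grad):
            if self.requires_grad:
                self._accum(grad @ np.swapaxes(b, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(a, -1, -2) @ grad)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- pointwise nonlinearities ----------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            self._accum(grad * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(grad):
            self._accum(grad / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad):
            self._accum(grad * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def backward(grad):
            self._accum(grad * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(grad):
            self._accum(grad * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(grad):
            self._accum(grad * factor)

        return Tensor._from_op(self.data * factor, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)

        def backward(grad):
            self._accum(grad * _sigmoid(self.data))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions / shaping ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(grad):
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(grad):
            self._accum(grad.reshape(orig))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(grad):
            self._accum(grad.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key))

        def backward(grad):
            g = np.zeros_like(self.data)
            if basic:  # basic indexing never repeats elements
                g[key] += grad
            else:
                np.add.at(g, key, grad)
            self._accum(g)

        return Tensor._from_op(out_data, (self,), backward)

    def take(self, indices: np.ndarray):
        """Gather rows (axis 0); gradient scatter-adds back."""
        indices = np.asarray(indices)
        out_data = self.data[indices]

        def backward(grad):
            g = np.zeros_like(self.data)
            _scatter_add(g, indices, grad)
            self._accum(g)

        return Tensor._from_op(out_data, (self,), backward)

    def item(self) -> float:
        return float(self.data)

    # -- backward pass -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                stack_.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * grad.ndim
            idx[axis] = slice(lo, hi)
            t._accum(grad[tuple(idx)])

    return Tensor._from_op(out_data, tensors, backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._wrap(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis with learnable gain/bias."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2.0).mean(axis=-1, keepdims=True)
    normed = centered * (var + eps) ** -0.5
    return normed * gain + bias


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``segment_ids``."""
    segment_ids = np.asarray(segment_ids)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    _scatter_add(out_data, segment_ids, x.data)

    def backward(grad):
        x._accum(grad[segment_ids])

    return Tensor._from_op(out_data, (x,), backward)


def segment_mean(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    total = segment_sum(x, segment_ids, num_segments)
    shape = (num_segments,) + (1,) * (x.ndim - 1)
    return total * Tensor(1.0 / counts.reshape(shape))


def segment_max(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Elementwise max per segment (subgradient shared across ties)."""
    segment_ids = np.asarray(segment_ids)
    out_data = np.full((num_segments,) + x.data.shape[1:], -np.inf)
    np.maximum.at(out_data, segment_ids, x.data)
    present = np.bincount(segment_ids, minlength=num_segments) > 0
    out_data[~present] = 0.0

    def backward(grad):
        mask = (x.data == out_data[segment_ids]).astype(np.float64)
        x._accum(grad[segment_ids] * mask)

    return Tensor._from_op(out_data, (x,), backward)


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a 1-D score vector within each segment."""
    segment_ids = np.asarray(segment_ids)
    # subtract per-segment max (constant shift) for numerical stability
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.data)
    shifted = scores - Tensor(seg_max[segment_ids])
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / denom.take(segment_ids)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout; identity when ``training`` is False or rate is 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
    return x * Tensor(mask)


def xavier_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> Tensor:
    """Glorot-uniform initialised parameter tensor."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    if len(shape) > 2:  # per-relation stacks: treat trailing two dims as the map
        fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stalls."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 min_lr: float = 1e-6):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> None:
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
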