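"""Minimal reverse-mode automatic differentiation over numpy arrays.

The auto-metric graph network is a small model (two graph layers, a pairwise
metric network and a linear head), but its adjacency is recomputed from the
current node representations at every layer, so hand-derived gradients would
be brittle.  This module provides a tape-based :class:`Tensor` with exactly
the primitives that model needs — broadcasting arithmetic, batched matmul,
``abs``, reductions, ``sigmoid``/``leaky_relu``, concatenation, slicing and a
softmax cross-entropy — plus an Adam optimizer.  Gradients are verified
against central finite differences in the test suite.

All data is float64; graphs are built only when an input requires gradients,
so inference-time forwards allocate no tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "cross_entropy_with_logits", "softmax"]


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction of derived nodes -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    # -- introspection ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def backward(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def backward(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def abs(self):
        sign = np.sign(self.data)

        def backward(g, a=self, s=sign):
            a._accum(g * s)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            a._accum(g * o)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, o=out_data):
            a._accum(g * o * (1.0 - o))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, slope)

        def backward(g, a=self, f=factor):
            a._accum(g * f)

        return Tensor._make(self.data * factor, (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        def backward(g, a=self):
            a._accum(g.reshape(a.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self, i=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, i, g)
            a._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- autodiff driver -------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[ax] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax for inference-time probabilities."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer `labels` under `logits` (..., C)."""
    n_class = logits.shape[-1]
    flat = logits.reshape(-1, n_class)
    labels = np.asarray(labels).reshape(-1)
    shift = Tensor(flat.data.max(axis=-1, keepdims=True))  # constant: max-shift for stability
    z = flat - shift
    lse = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - lse
    picked = logp[(np.arange(labels.size), labels)]
    return -picked.mean()


class Adam:
    """Adam optimizer over a name -> Tensor parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            m_hat = self._m[k] / (1 - b1**self.t)
            v_hat = self._v[k] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
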