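"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Only the operations needed by the tree-traversal network are provided:
broadcasting arithmetic, (batched) matmul, ReLU, exp/log/sqrt, reductions,
concatenation/stacking, reshape/transpose, a numerically stable masked
softmax, and a fused binary cross-entropy-with-logits loss.  Gradients are
accumulated by topological traversal of the recorded graph.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "bce_with_logits", "Adam"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""

    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: Tuple["Tensor", ...] = ()

    # -- construction of graph nodes ----------------------------------------

    @staticmethod
    def _op(data: np.ndarray, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in prev)
        if out.requires_grad:
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.shape),
            )

        return Tensor._op(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g, out):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._op(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities -----------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g, out: (g * mask,))

    def exp(self):
        def backward(g, out):
            return (g * out.data,)

        return Tensor._op(np.exp(self.data), (self,), backward)

    def log(self):
        return Tensor._op(np.log(self.data), (self,), lambda g, out: (g / self.data,))

    def sqrt(self):
        def backward(g, out):
            return (g * 0.5 / out.data,)

        return Tensor._op(np.sqrt(self.data), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor._op(s, (self,), lambda g, out: (g * s * (1.0 - s),))

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum over *axis*; gradient flows to the first argmax."""

        idx = np.argmax(self.data, axis=axis)

        def backward(g, out):
            grad = np.zeros_like(self.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), gg, axis=axis
            )
            return (grad,)

        return Tensor._op(self.data.max(axis=axis, keepdims=keepdims), (self,), backward)

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape
        return Tensor._op(
            self.data.reshape(*shape), (self,), lambda g, out: (g.reshape(old),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._op(
            self.data.transpose(*axes), (self,), lambda g, out: (g.transpose(*inv),)
        )

    def __getitem__(self, key):
        def backward(g, out):
            grad = np.zeros_like(self.data)
            np.add.at(grad, key, g)
            return (grad,)

        return Tensor._op(self.data[key], (self,), backward)

    # -- autodiff driver ------------------------------------------------------

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
            grad = np.ones_like(self.data)

        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))

        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            for p, pg in zip(node._prev, node._backward(g, node)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# Free functions
# ---------------------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)

    def backward(g, out):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return Tensor._op(np.stack([t.data for t in tensors], axis=axis), tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max-shift is treated as a constant,
    which leaves the gradient exact because softmax is shift-invariant."""

    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logits: Tensor, targets: np.ndarray, mask=None) -> Tensor:
    """Mean binary cross-entropy over unmasked entries, from logits.

    Stable form: loss = max(z, 0) - z*y + log(1 + exp(-|z|)).
    """

    y = np.asarray(targets, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(y)
    m = np.asarray(mask, dtype=np.float64)
    count = m.sum()
    if count == 0:
        raise ValueError("no unmasked entries in loss")
    z = logits.data
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    value = (per * m).sum() / count

    def backward(g, out):
        p = 1.0 / (1.0 + np.exp(-z))
        return (g * (p - y) * m / count,)

    return Tensor._op(np.array(value), (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
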