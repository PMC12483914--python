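"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core the fusion network (:mod:`sulfsite.fusionnet`) is
built on: a tape-based ``Tensor`` supporting the handful of differentiable
operations a gated recurrent network with attention needs — broadcasting
arithmetic, (batched) matrix products, sigmoid/tanh/softmax, reductions,
concatenation/stacking/slicing and a numerically stable binary cross-entropy
on logits — plus an Adam optimizer.

Gradients follow the standard vector-Jacobian-product rules; broadcasting is
handled by summing gradients back to the operand's shape.  All operations are
deterministic, so a fixed seed for parameter initialisation and data order
yields bit-identical training runs on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "bce_with_logits", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # sum away leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ---------------------------------------------------------------- utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=parents if req else (),
                      _backward=backward if req else None)

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g / b.data, a.data.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other
        out_data = np.matmul(a.data, b.data)

        def backward(g):
            if b.data.ndim == 1:
                ga = np.multiply.outer(g, b.data) if a.data.ndim > 1 else g * b.data
                gb = np.matmul(a.data.swapaxes(-1, -2), g) if a.data.ndim > 1 else g * a.data
                return (_unbroadcast(np.asarray(ga), a.data.shape),
                        _unbroadcast(np.asarray(gb), b.data.shape))
            ga = np.matmul(g, b.data.swapaxes(-1, -2))
            gb = np.matmul(a.data.swapaxes(-1, -2), g)
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return self._make(out_data, (self, other), backward)

    # --------------------------------------------------------- nonlinearity
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return self._make(t, (self,), lambda g: (g * (1.0 - t * t),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        e = np.exp(self.data)
        return self._make(e, (self,), lambda g: (g * e,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        return self._make(s, (self,), backward)

    # ------------------------------------------------------------ reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return self._make(self.data.reshape(shape), (self,),
                          lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: (g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        return self._make(self.data.swapaxes(a, b), (self,),
                          lambda g: (g.swapaxes(a, b),))

    def __getitem__(self, idx):
        out_data = self.data[idx]
        # basic indexing (ints/slices) selects disjoint elements: plain +=
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (int, slice, type(None), type(Ellipsis)))
                    for p in parts)

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------ reduction
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    # closures never mutate returned arrays in place, so
                    # aliasing (views of the child's grad) is safe here
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  _parents=tuple(tensors) if req else (),
                  _backward=backward if req else None)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  _parents=tuple(tensors) if req else (),
                  _backward=backward if req else None)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits, numerically stable.

    loss = mean( max(z,0) - z*y + log(1 + exp(-|z|)) );  d/dz = (sigmoid(z)-y)/n.
    """
    z = logits.data
    y = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out_data = loss.mean()
    n = z.size

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-z))
        return (g * (s - y) / n,)

    req = logits.requires_grad
    return Tensor(out_data, requires_grad=req,
                  _parents=(logits,) if req else (),
                  _backward=backward if req else None)


class Adam:
    """Adaptive-moment SGD over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
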