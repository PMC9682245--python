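"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` replays the tape in reverse topological
order.  Only the primitives needed by the models in this package are
implemented (broadcast arithmetic, batched matmul, softmax, layer norm,
activations, gather/concatenate, stable binary cross-entropy).  Gradients are
accumulated in ``Tensor.grad`` as plain arrays.

The dtype of a tensor follows its data; parameters default to float32, while
float64 graphs are supported for high-precision equivalence checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: incoming buffers may be shared with other graph edges
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    @staticmethod
    def _lift(other, dtype) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=dtype))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: "Tensor"):
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other, self.dtype)
        a, b = self, other
        out = self._make(a.data + b.data, (a, b), None)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def backward(g):
            self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._lift(other, self.dtype))

    def __rsub__(self, other):
        return self._lift(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.dtype)
        a, b = self, other
        out = self._make(a.data * b.data, (a, b), None)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other, self.dtype)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other, self.dtype) * self ** -1.0

    def __pow__(self, exponent: float):
        out = self._make(self.data ** exponent, (self,), None)

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other, self.dtype)
        a, b = self, other
        out = self._make(a.data @ b.data, (a, b), None)

        def backward(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        out._backward = backward
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * y)

        out._backward = backward
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            self._accumulate(g / self.data)

        out._backward = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * (1.0 - y * y))

        out._backward = backward
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * y * (1.0 - y))

        out._backward = backward
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def backward(g):
            self._accumulate(g * mask)

        out._backward = backward
        return out

    def gelu(self):
        # sigmoid approximation of the Gaussian error linear unit
        x = self.data
        s = 1.0 / (1.0 + np.exp(-1.702 * x))
        y = x * s
        out = self._make(y, (self,), None)

        def backward(g):
            self._accumulate(g * (s + 1.702 * x * s * (1.0 - s)))

        out._backward = backward
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = self._make(out_data, (self,), None)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape).copy()
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                grad = np.broadcast_to(g, self.data.shape).copy()
            self._accumulate(grad)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = self._make(self.data.reshape(shape), (self,), None)

        def backward(g):
            self._accumulate(g.reshape(orig))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int):
        out = self._make(np.swapaxes(self.data, a, b), (self,), None)

        def backward(g):
            self._accumulate(np.swapaxes(g, a, b))

        out._backward = backward
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = self._make(np.transpose(self.data, axes), (self,), None)

        def backward(g):
            self._accumulate(np.transpose(g, inv))

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            self._accumulate(grad)

        out._backward = backward
        return out

    # -- fused ops ---------------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)
        out = self._make(y, (self,), None)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = backward
        return out

    def layer_norm(self, eps: float = 1e-5):
        """Normalize over the last axis to zero mean / unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = self._make(y, (self,), None)
        n = self.data.shape[-1]

        def backward(g):
            gy = (g * y).sum(axis=-1, keepdims=True)
            gm = g.sum(axis=-1, keepdims=True)
            self._accumulate(inv * (g - gm / n - y * gy / n))

        out._backward = backward
        return out

    def bce_with_logits(self, targets: np.ndarray):
        """Elementwise numerically-stable binary cross-entropy on logits."""
        z = self.data
        t = np.asarray(targets, dtype=z.dtype)
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        out = self._make(loss, (self,), None)

        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-z))
            self._accumulate(g * (sig - t))

        out._backward = backward
        return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if not out.requires_grad:
        return out
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    out._prev = tuple(tensors)
    out._backward = backward
    return out
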