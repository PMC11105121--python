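"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` records the operations that produced it; calling
``backward()`` on a scalar loss accumulates gradients into every upstream
tensor created with ``requires_grad=True``.  Supported operations are the
ones the package's architectures need: broadcasting arithmetic, matmul
(including batched), elementwise nonlinearities, reductions, reshape /
transpose / concat / slicing, valid 1-D convolution, and a fused
softmax + cross-entropy loss.  Gradient correctness is pinned by finite-
difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ---- graph -----------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += _unbroadcast(grad, self.data.shape)

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g * other.data), other._accum(g * self.data))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, parents=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1.0))
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = backward
        return out

    # ---- nonlinearities --------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -500, 500))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    # ---- reductions and shape -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        m = Tensor(self.data.max(axis=axis, keepdims=True))  # constant shift
        e = (self - m).exp()
        return e * e.sum(axis=axis, keepdims=True).pow(-1.0)

    def conv1d(self, weight: "Tensor") -> "Tensor":
        """Valid 1-D convolution: (B, T, C) with (K, C, F) -> (B, T-K+1, F)."""
        x, w = self.data, weight.data
        K = w.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(x, K, axis=1)  # (B, L, C, K)
        out = Tensor(np.einsum("blck,kcf->blf", win, w), parents=(self, weight))

        def backward(g):
            weight._accum(np.einsum("blck,blf->kcf", win, g))
            gx = np.zeros_like(x)
            L = g.shape[1]
            for k in range(K):
                gx[:, k : k + L, :] += g @ w[k].T
            self._accum(gx)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = backward
    return out


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) against one-hot targets."""
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    n = logits.data.shape[0]
    loss_val = -np.sum(onehot * np.log(np.clip(probs, 1e-12, None))) / n
    out = Tensor(loss_val, parents=(logits,))
    out._backward = lambda g: logits._accum(g * (probs - onehot) / n)
    return out
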