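"""Minimal vectorized reverse-mode automatic differentiation over numpy.

Supports exactly the operations the package's neural components need:
broadcasting add/sub/mul/div, matmul (either operand may be a constant
ndarray), ReLU, powers, axis reductions, row gathering, column concatenation
and a fused softmax cross-entropy.  Gradients flow only into ``Tensor``
leaves created with ``requires_grad=True`` (parameters); plain ndarrays are
treated as constants.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer ndarray <op> Tensor to the reflected operators
    __array_priority__ = 100.0
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g * other.data),
            other._accum(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1.0)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g @ other.data.T),
            other._accum(self.data.T @ g),
        )
        return out

    def __rmatmul__(self, other):
        return self._lift(other) @ self

    # -- nonlinearity & reductions ----------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0.0))
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shaping -----------------------------------------------------------
    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], parents=(self,))

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            self._accum(grad)

        out._backward = backward
        return out

    @staticmethod
    def concat_cols(parts: list["Tensor"]):
        parts = [Tensor._lift(p) for p in parts]
        widths = [p.data.shape[1] for p in parts]
        out = Tensor(np.concatenate([p.data for p in parts], axis=1), parents=tuple(parts))

        def backward(g):
            offset = 0
            for p, w in zip(parts, widths):
                p._accum(g[:, offset : offset + w])
                offset += w

        out._backward = backward
        return out

    # -- losses ------------------------------------------------------------
    def cross_entropy(self, labels: np.ndarray):
        """Mean softmax cross-entropy; ``labels`` are integer class indices."""
        labels = np.asarray(labels, dtype=np.intp)
        z = self.data - self.data.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
        log_probs = z - logsumexp
        n = self.data.shape[0]
        loss_val = -log_probs[np.arange(n), labels].mean()
        out = Tensor(loss_val, parents=(self,))
        softmax = np.exp(log_probs)

        def backward(g):
            grad = softmax.copy()
            grad[np.arange(n), labels] -= 1.0
            self._accum(float(g) * grad / n)

        out._backward = backward
        return out

    # -- engine ------------------------------------------------------------
    def backward(self):
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        while stack:
            node, parents = stack[-1]
            advanced = False
            for p in parents:
                if id(p) not in seen:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(rng: np.random.Generator, shape: tuple[int, ...], scale: float | None = None) -> Tensor:
    """Gaussian-initialized trainable tensor (Glorot-style scale by default)."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


def zeros_parameter(shape: tuple[int, ...]) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class Adam:
    """Standard Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

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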