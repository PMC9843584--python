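"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

This exists because the reference CNN / transformer models need gradients and
no deep-learning framework is a dependency of this package. It implements
only the primitives those models use: broadcast arithmetic, batched matmul,
ReLU, softmax, reductions, reshapes, embedding lookup, 1-D convolution
(im2col, 'same' padding), max pooling, dropout and the two losses. Gradients
of every primitive are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers ----------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (), backward=backward if req else None)

    # ---- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = self._node(self.data + other.data, (self, other), None)
        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)
        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._node(-self.data, (self,), None)
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = self._node(self.data * other.data, (self, other), None)
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = self._node(self.data / other.data, (self, other), None)
        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )
        out._backward = backward
        return out

    def pow(self, exponent: float):
        out = self._node(self.data**exponent, (self,), None)
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out = self._node(np.matmul(self.data, other.data), (self, other), None)
        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.data.shape), _unbroadcast(gb, other.data.shape)
        out._backward = backward
        return out

    __matmul__ = matmul

    # ---- nonlinearities ----------------------------------------------------

    def relu(self):
        keep = self.data > 0
        out = self._node(np.where(keep, self.data, 0.0), (self,), None)
        out._backward = lambda g: (g * keep,)
        return out

    def exp(self):
        value = np.exp(self.data)
        out = self._node(value, (self,), None)
        out._backward = lambda g: (g * value,)
        return out

    def sigmoid(self):
        value = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = self._node(value, (self,), None)
        out._backward = lambda g: (g * value * (1.0 - value),)
        return out

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)
        out = self._node(s, (self,), None)
        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)
        out._backward = backward
        return out

    # ---- reductions / reshapes --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.data.shape).copy(),)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = self._node(self.data.reshape(*shape), (self,), None)
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def transpose(self, *axes):
        out = self._node(self.data.transpose(*axes), (self,), None)
        inv = np.argsort(axes)
        out._backward = lambda g: (g.transpose(*inv),)
        return out

    # ---- structured ops ----------------------------------------------------

    def embedding(self, ids: np.ndarray):
        """Row gather: self is (V, D) weights, ids an integer array."""
        ids = np.asarray(ids)
        out = self._node(self.data[ids], (self,), None)
        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, ids.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            return (grad,)
        out._backward = backward
        return out

    def conv1d_same(self, weight: "Tensor", bias: "Tensor"):
        """1-D convolution with 'same' zero padding.

        self: (B, C, L); weight: (F, C, K); bias: (F,). Output (B, F, L).
        """
        x, w = self.data, weight.data
        B, C, L = x.shape
        F, _, K = w.shape
        left = (K - 1) // 2
        right = K - 1 - left
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        # im2col: (B, L, C*K)
        cols = np.empty((B, L, C * K))
        for k in range(K):
            cols[:, :, k::K] = np.swapaxes(xp[:, :, k : k + L], 1, 2)
        wcol = w.reshape(F, C * K)  # row f = [c0k0, c0k1, ..., c1k0, ...]
        out_data = np.matmul(cols, wcol.T) + bias.data  # (B, L, F)
        out_data = np.swapaxes(out_data, 1, 2)  # (B, F, L)
        out = self._node(out_data, (self, weight, bias), None)

        def backward(g):
            gl = np.swapaxes(g, 1, 2)  # (B, L, F)
            g_bias = gl.sum(axis=(0, 1))
            g_wcol = np.einsum("blf,blk->fk", gl, cols)
            g_cols = np.matmul(gl, wcol)  # (B, L, C*K)
            g_xp = np.zeros_like(xp)
            for k in range(K):
                g_xp[:, :, k : k + L] += np.swapaxes(g_cols[:, :, k::K], 1, 2)
            g_x = g_xp[:, :, left : left + L]
            return g_x, g_wcol.reshape(w.shape), g_bias

        out._backward = backward
        return out

    def maxpool1d(self, kernel: int = 2):
        """Max pooling over the last axis, stride == kernel, floor division."""
        x = self.data
        B, C, L = x.shape
        Lo = L // kernel
        view = x[:, :, : Lo * kernel].reshape(B, C, Lo, kernel)
        arg = view.argmax(axis=-1)
        out = self._node(view.max(axis=-1), (self,), None)

        def backward(g):
            grad = np.zeros_like(x)
            b, c, o = np.indices(arg.shape)
            grad[b, c, o * kernel + arg] = g
            return (grad,)

        out._backward = backward
        return out

    def dropout(self, p: float, rng: np.random.Generator, train: bool):
        if not train or p <= 0.0:
            return self
        keep = rng.random(self.data.shape) >= p
        scale = 1.0 / (1.0 - p)
        out = self._node(self.data * keep * scale, (self,), None)
        out._backward = lambda g: (g * keep * scale,)
        return out

    def add_const(self, const: np.ndarray):
        """Add a non-differentiable constant array (e.g. positional encoding,
        attention mask logits)."""
        out = self._node(self.data + const, (self,), None)
        out._backward = lambda g: (g,)
        return out

    # ---- losses ------------------------------------------------------------

    def mse_loss(self, target: np.ndarray):
        diff = self - Tensor(target)
        return diff.pow(2).mean()

    def bce_with_logits(self, target: np.ndarray, weights: np.ndarray | None = None):
        """Numerically stable binary cross entropy on logits (mean reduction)."""
        z, y = self.data, np.asarray(target, dtype=np.float64)
        w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=np.float64)
        loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
        out = self._node((w * loss).sum() / w.sum(), (self,), None)
        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            return (g * w * (sig - y) / w.sum(),)
        out._backward = backward
        return out

    # ---- backward pass -----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` tensor."""
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
            for parent in node._parents:
                stack.append((parent, False))

        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data) if grad is None else np.asarray(grad)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for parent, pg in zip(node._parents, parent_grads):
                if not parent.requires_grad:
                    continue
                if parent._backward is None and not parent._parents:
                    parent.grad = pg if parent.grad is None else parent.grad + pg
                else:
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
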