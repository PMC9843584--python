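"""Neural-network layers built on the autograd engine.

Only what the reference models need: linear, embedding with a frozen PAD row,
sinusoidal positional encoding, 1-D convolution + batch norm + max pooling,
layer norm, multi-head self-attention with key padding mask, and a
transformer encoder layer. Weight initialization follows the usual
fan-in-scaled uniform scheme.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "Conv1dSame",
    "BatchNorm1d",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerEncoderLayer",
    "positional_encoding",
]


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, training: bool) -> None:
        self.training = training
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(training)

    def state(self) -> list[np.ndarray]:
        """Copies of all parameter arrays plus buffers (for checkpointing)."""
        arrays = [p.data.copy() for p in self.parameters()]
        arrays.extend(b.copy() for b in self._buffers())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays):
            p.data = a.copy()
        for b, a in zip(self._buffers(), arrays[len(params):]):
            b[...] = a

    def _buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                bufs.extend(value._buffers())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        bufs.extend(item._buffers())
        bufs.extend(getattr(self, "_own_buffers", []))
        return bufs


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(n_out,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Embedding(Module):
    """Token embedding; row 0 (PAD) is zero-initialized like any other row but
    padded positions are masked out downstream, so its value is irrelevant."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n_tokens, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight.embedding(ids)


def positional_encoding(max_len: int, dim: int) -> np.ndarray:
    """Sinusoidal position encodings, shape (max_len, dim)."""
    position = np.arange(max_len)[:, None]
    div = np.exp(np.arange(0, dim, 2) * (-np.log(10000.0) / dim))
    pe = np.zeros((max_len, dim))
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div[: dim // 2])
    return pe


class Conv1dSame(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_out, c_in, kernel)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=(c_out,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d_same(self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch norm over (B, C, L); running stats for eval mode."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, n_channels, 1)))
        self.beta = Parameter(np.zeros((1, n_channels, 1)))
        self.running_mean = np.zeros((1, n_channels, 1))
        self.running_var = np.ones((1, n_channels, 1))
        self._own_buffers = [self.running_mean, self.running_var]
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = xc.pow(2).mean(axis=(0, 2), keepdims=True)
            self.running_mean[...] = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var[...] = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            xhat = (x + Tensor(-self.running_mean)) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((dim,)))
        self.beta = Parameter(np.zeros((dim,)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = xc.pow(2).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with a key padding mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"embedding dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, T, D = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, hd).transpose(0, 2, 1, 3)  # (B, H, T, hd)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))  # (B,H,T,T)
        # mask PAD keys: large negative logit, broadcast over heads and queries
        neg = np.where(pad_mask[:, None, None, :], -1e9, 0.0)
        attn = scores.add_const(neg).softmax(axis=-1)
        ctx = attn.matmul(v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention and position-wise feed-forward,
    each wrapped in residual + layer norm, with dropout."""

    def __init__(
        self,
        dim: int,
        n_heads: int,
        hidden_dim: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm1 = LayerNorm(dim)
        self.ff1 = Linear(dim, hidden_dim, rng)
        self.ff2 = Linear(hidden_dim, dim, rng)
        self.norm2 = LayerNorm(dim)
        self.dropout = dropout

    def __call__(self, x: Tensor, pad_mask: np.ndarray, rng: np.random.Generator) -> Tensor:
        a = self.attn(x, pad_mask).dropout(self.dropout, rng, self.training)
        x = self.norm1(x + a)
        f = self.ff2(self.ff1(x).relu()).dropout(self.dropout, rng, self.training)
        return self.norm2(x + f)
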