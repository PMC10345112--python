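"""Neural-network building blocks: dense layers, layer norm, multi-head
self-attention, post-norm transformer encoder layers, sinusoidal positional
encoding, and a bidirectional LSTM summarizer.

All layers hold their parameters as autodiff Tensors and expose them through
``parameters()``.  Initialization is driven by an explicit numpy Generator so
that model construction is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .autodiff import Tensor, concat

NEG_INF = -1e9  # additive attention mask value; exp() underflows to exactly 0


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: Optional[tuple] = None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Dense(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 activation: Optional[str] = None):
        self.w = Tensor(glorot(rng, d_in, d_out), requires_grad=True, name="w")
        self.b = Tensor(np.zeros(d_out), requires_grad=True, name="b")
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w + self.b
        if self.activation == "relu":
            y = y.relu()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True, name="gamma")
        self.beta = Tensor(np.zeros(dim), requires_grad=True, name="beta")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


def positional_encoding(length: int, dim: int) -> np.ndarray:
    """Standard sine/cosine positional signal, shape (length, dim).

    Even channels carry sin(pos / 10000^(2i/dim)), odd channels the cosine
    at the same frequency, so every position below ~10^4 gets a unique code.
    """
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, 2.0 * i / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle[:, : dim - dim // 2])
    return enc


def positional_encode(x: Tensor) -> Tensor:
    """Add the sinusoidal position signal to a (..., T, D) tensor."""
    T, D = x.shape[-2], x.shape[-1]
    return x + positional_encoding(T, D)


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with an additive key mask."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads, self.d_head = dim, n_heads, dim // n_heads
        self.wq = Dense(rng, dim, dim)
        self.wk = Dense(rng, dim, dim)
        self.wv = Dense(rng, dim, dim)
        self.wo = Dense(rng, dim, dim)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, D) -> (B, H, T, d_head)
        return x.reshape(B, T, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """x: (B, T, D); mask: (B, T) boolean, True = attend."""
        B, T, D = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(self.d_head))
        bias = np.where(mask[:, None, None, :], 0.0, NEG_INF)
        attn = (scores + bias).softmax(axis=-1)
        ctx = attn @ v  # (B, H, T, d_head)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape(B, T, D)
        return self.wo(ctx)


class TransformerLayer(Module):
    """Post-norm encoder layer: x -> LN(x + MHA(x)) -> LN(. + FFN(.))."""

    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int,
                 ffn_dim: int):
        self.attn = MultiHeadAttention(rng, dim, n_heads)
        self.ln1 = LayerNorm(dim)
        self.ffn1 = Dense(rng, dim, ffn_dim, activation="relu")
        self.ffn2 = Dense(rng, ffn_dim, dim)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.attn(x, mask))
        x = self.ln2(x + self.ffn2(self.ffn1(x)))
        return x


class TransformerStack(Module):
    def __init__(self, rng: np.random.Generator, dim: int, n_heads: int,
                 ffn_dim: int, n_layers: int):
        self.layers = [TransformerLayer(rng, dim, n_heads, ffn_dim)
                       for _ in range(n_layers)]

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        for layer in self.layers:
            x = layer(x, mask)
        return x


class BiLSTM(Module):
    """Bidirectional LSTM whose final hidden states summarize a sequence.

    The forward and backward passes each produce a hidden state of size
    ``hidden``; their concatenation (2*hidden) is the fixed-length summary.
    """

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        self.cells = [_LSTMCell(rng, d_in, hidden) for _ in range(2)]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, d_in) -> (B, 2*hidden) final-state summary."""
        B, T, _ = x.shape
        h_fwd = self.cells[0].run(x, range(T))
        h_bwd = self.cells[1].run(x, range(T - 1, -1, -1))
        return concat([h_fwd, h_bwd], axis=-1)


class _LSTMCell(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        d = d_in + hidden
        self.w = Tensor(glorot(rng, d, 4 * hidden), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def run(self, x: Tensor, order) -> Tensor:
        B = x.shape[0]
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for t in order:
            z = concat([x[:, t, :], h], axis=-1) @ self.w + self.b
            i = z[:, :H].sigmoid()
            f = z[:, H: 2 * H].sigmoid()
            g = z[:, 2 * H: 3 * H].tanh()
            o = z[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h
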