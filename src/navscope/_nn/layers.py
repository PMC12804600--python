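"""Neural-network building blocks on the numpy autograd.

Covers what the decoders need: linear / layer-norm / dropout, a transformer
encoder with padding-masked multi-head self-attention and a learned [CLS]
token, a (bi)directional LSTM, and a same-padded temporal convolution.
Parameter initialization is fan-in uniform, seeded per module for exact
reproducibility.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters ignore the grad-mode flag at creation


class Module:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    k = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-k, k, size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Parameter(_uniform(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Parameter(np.ones(dim))
        self.b = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return x.dropout(self.p, self.rng, self.training)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with an additive padding mask."""

    def __init__(self, d_model: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, pad_mask: np.ndarray | None = None) -> Tensor:
        B, T, D = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(self.dh))
        if pad_mask is not None:  # True where padded -> masked out of attention
            bias = np.where(pad_mask, -1e9, 0.0)[:, None, None, :]
            scores = scores + bias
        att = self.drop(scores.softmax(axis=-1))
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: attention and feed-forward, each with residual."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, dropout, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln2 = LayerNorm(d_model)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, pad_mask=None) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, pad_mask)))
        x = self.ln2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class LSTM(Module):
    """Single-layer LSTM; returns the full hidden sequence (B, T, H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.H = d_hidden
        self.Wx = Parameter(_uniform(rng, (d_in, 4 * d_hidden), d_in))
        self.Wh = Parameter(_uniform(rng, (d_hidden, 4 * d_hidden), d_hidden))
        self.b = Parameter(np.zeros(4 * d_hidden))

    def forward(self, x: Tensor, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        H = self.H
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outs = [None] * T
        for t in steps:
            gates = x[:, t, :] @ self.Wx + h @ self.Wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h.reshape(B, 1, H)
        return concatenate(outs, axis=1)


class BiLSTM(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, d_hidden, rng)
        self.bwd = LSTM(d_in, d_hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        return concatenate([self.fwd(x), self.bwd(x, reverse=True)], axis=-1)


class Conv1d(Module):
    """Temporal convolution over (B, T, C) with 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.W = [Parameter(_uniform(rng, (c_in, c_out), c_in * kernel))
                  for _ in range(kernel)]
        self.b = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        B, T, C = x.shape
        half = self.kernel // 2
        zeros = Tensor(np.zeros((B, half, C)))
        xp = concatenate([zeros, x, zeros], axis=1)
        out = xp[:, 0:T, :] @ self.W[0]
        for j in range(1, self.kernel):
            out = out + xp[:, j:j + T, :] @ self.W[j]
        return out + self.b
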