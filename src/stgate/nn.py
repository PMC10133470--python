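"""Neural-network building blocks used by the STGATE model.

Layers are thin ``Module`` wrappers over :mod:`stgate.autodiff` operations:
linear and 2-D convolution layers, layer/batch normalization, dropout, a
pre-norm transformer encoder with a learned positional embedding, and the Adam
optimizer.  All random initialization draws from an explicitly passed
``numpy.random.Generator`` so model construction is fully seeded.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Parameter, Tensor, conv2d, softmax


class Module:
    """Base class with recursive parameter registry and train/eval modes."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(glorot(rng, (in_features, out_features), in_features, out_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.weight = Parameter(glorot(rng, (out_channels, in_channels, kh, kw), fan_in, fan_out))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode.  Needs a seeded generator."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without a generator")
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        centered = x - m
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps) ** 0.5 * self.gamma + self.beta


class ScalarBatchNorm(Module):
    """Batch normalization treating the whole input tensor as one channel.

    This is the mini-batch standardization applied to the spatial/temporal
    attention score tensors: mean and population variance are taken over every
    entry of the batch, with scalar learnable affine parameters and running
    statistics for evaluation mode.
    """

    def __init__(self, eps: float = 1e-5, momentum: float = 0.1, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(()))
            self.beta = Parameter(np.zeros(()))
        self.running_mean = 0.0
        self.running_var = 1.0

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean()
            var = ((x - m) ** 2).mean()
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * float(m.data)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * float(var.data)
            out = (x - m) / (var + self.eps) ** 0.5
        else:
            out = (x - self.running_mean) * (1.0 / math.sqrt(self.running_var + self.eps))
        if self.affine:
            out = out * self.gamma + self.beta
        return out


class MultiheadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"model width {dim} not divisible by head count {heads}")
        self.heads = heads
        self.head_dim = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)
        self._last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        batch, seq, dim = x.shape
        h, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(batch, seq, h, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        att = softmax(scores, axis=-1)
        self._last_attention = att.data
        mixed = att @ v  # (B, h, seq, hd)
        merged = mixed.transpose(0, 2, 1, 3).reshape(batch, seq, dim)
        return self.out(merged)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, heads: int, ff_width: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.drop1 = Dropout(dropout, rng=None)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_width, rng)
        self.ff2 = Linear(ff_width, dim, rng)
        self.drop2 = Dropout(dropout, rng=None)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.ln1(x)))
        x = x + self.drop2(self.ff2(self.ff1(self.ln2(x)).relu()))
        return x


class TransformerEncoder(Module):
    """Learned positional embedding followed by ``depth`` pre-norm layers.

    Depth 0 reduces to adding the positional embedding.
    """

    def __init__(self, seq_len: int, dim: int, depth: int, heads: int, ff_width: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(seq_len, dim)))
        self.layers = [
            TransformerEncoderLayer(dim, heads, ff_width, dropout, rng)
            for _ in range(depth)
        ]

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.pos
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
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

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def set_dropout_rng(module: Module, rng: np.random.Generator) -> None:
    """Point every Dropout in ``module`` at a shared seeded generator."""
    for m in module.modules():
        if isinstance(m, Dropout):
            m.rng = rng
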