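"""Neural-network layers built on the autograd engine.

Conventions follow the common deep-learning framework defaults this
package documents in its methods note: linear and convolutional weights
are initialized uniformly in ``±1/sqrt(fan_in)``, recurrent weights in
``±1/sqrt(H)``, nucleotide embeddings from a standard normal with the PAD
row frozen at zero, batch normalization uses eps 1e-5 and running-stat
momentum 0.1, and dropout uses inverted scaling.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Parameter, Tensor, concat


class Module:
    """Composable container with recursive parameter/mode handling."""

    training: bool = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for m in self.modules():
            for k, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    yield f"{type(m).__name__}.{k}", v

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def set_rng(self, rng: np.random.Generator):
        """Attach a generator to every stochastic layer (dropout)."""
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng):
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features))
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.swapaxes(0, 1) + self.bias


class BatchNorm(Module):
    """Normalizes the trailing feature axis over all leading axes.

    Covers the 1-d case (B, F), the sequence case (B, T, F) with
    statistics over B*T, and the channels-last image case (B, H, W, C).
    Running statistics use the unbiased variance; normalization inside a
    training step uses the biased one.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            n = x.data.size // x.data.shape[-1]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - self.running_mean) * (
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float = 0.1):
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = self.rng.random(x.shape) >= self.p
        return x * (keep / (1.0 - self.p))


class Embedding(Module):
    """Token embedding with the PAD row (id 0) frozen at the zero vector."""

    def __init__(self, num_embeddings: int, dim: int, rng, pad_id: int = 0):
        w = rng.normal(size=(num_embeddings, dim))
        w[pad_id] = 0.0
        self.weight = Parameter(w)
        self.pad_id = pad_id
        self.dim = dim

    @property
    def n_trainable(self) -> int:
        """Parameter count excluding the frozen PAD row."""
        return (self.weight.data.shape[0] - 1) * self.dim

    def forward(self, tokens: np.ndarray) -> Tensor:
        w = self.weight
        pad_id = self.pad_id

        def backward(g):
            full = np.zeros_like(w.data)
            np.add.at(full, tokens.reshape(-1), g.reshape(-1, g.shape[-1]))
            full[pad_id] = 0.0
            return (full,)

        return Tensor._from_op(w.data[tokens], (w,), backward)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def sinusoidal_positional_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed sin/cos positional code: pe[p, 2i] = sin(p / 10000^(2i/d))."""
    pe = np.zeros((length, dim))
    pos = np.arange(length)[:, None]
    div = np.exp(-math.log(10000.0) * np.arange(0, dim, 2) / dim)
    pe[:, 0::2] = np.sin(pos * div)
    pe[:, 1::2] = np.cos(pos * div)
    return pe


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with ``heads`` heads of size
    ``dim / heads`` (size 1 in this package, where dim == heads)."""

    def __init__(self, dim: int, heads: int, rng):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        bound = 1.0 / math.sqrt(dim)
        self.in_weight = Parameter(
            rng.uniform(-bound, bound, size=(3 * dim, dim))
        )
        self.in_bias = Parameter(np.zeros(3 * dim))
        self.out_weight = Parameter(
            rng.uniform(-bound, bound, size=(dim, dim))
        )
        self.out_bias = Parameter(np.zeros(dim))
        self.dim = dim
        self.heads = heads
        self.d_head = dim // heads

    def forward(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        qkv = x @ self.in_weight.swapaxes(0, 1) + self.in_bias
        h, d = self.heads, self.d_head

        def split(t: Tensor) -> Tensor:
            # (B, T, D) -> (B, heads, T, d_head)
            return t.reshape(B, T, h, d).swapaxes(1, 2)

        q = split(qkv[:, :, :D])
        k = split(qkv[:, :, D : 2 * D])
        v = split(qkv[:, :, 2 * D :])
        if d == 1:
            # head size 1: scores are outer products; broadcasting is much
            # cheaper than a stack of tiny matmuls
            scores = q.reshape(B, h, T, 1) * k.reshape(B, h, 1, T)
            att = scores.softmax(axis=-1)
            ctx = (att * v.reshape(B, h, 1, T)).sum(axis=-1)
            ctx = ctx.reshape(B, h, T, d)
        else:
            scores = (q @ k.swapaxes(2, 3)) * (1.0 / math.sqrt(d))
            att = scores.softmax(axis=-1)
            ctx = att @ v
        ctx = ctx.swapaxes(1, 2).reshape(B, T, D)
        return ctx @ self.out_weight.swapaxes(0, 1) + self.out_bias


class BiLSTM(Module):
    """One-layer bidirectional LSTM (no internal dropout).

    Gate order is (input, forget, cell, output); initial states are zero;
    the output concatenates the forward and backward hidden sequences to
    shape (B, T, 2H).
    """

    def __init__(self, input_size: int, hidden_size: int, rng):
        H = hidden_size
        bound = 1.0 / math.sqrt(H)

        def u(*shape):
            return Parameter(rng.uniform(-bound, bound, size=shape))

        self.w_ih_f = u(4 * H, input_size)
        self.w_hh_f = u(4 * H, H)
        self.b_ih_f = u(4 * H)
        self.b_hh_f = u(4 * H)
        self.w_ih_b = u(4 * H, input_size)
        self.w_hh_b = u(4 * H, H)
        self.b_ih_b = u(4 * H)
        self.b_hh_b = u(4 * H)
        self.hidden_size = H

    def _direction(self, x: Tensor, w_ih, w_hh, b_ih, b_hh, reverse: bool):
        B, T, _ = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        pre = x @ w_ih.swapaxes(0, 1) + b_ih  # (B, T, 4H), input part once
        outs: list[Tensor] = []
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            gates = pre[:, t, :] + h @ w_hh.swapaxes(0, 1) + b_hh
            i = gates[:, :H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, H))
        if reverse:
            outs.reverse()
        return concat(outs, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        fwd = self._direction(
            x, self.w_ih_f, self.w_hh_f, self.b_ih_f, self.b_hh_f, False
        )
        bwd = self._direction(
            x, self.w_ih_b, self.w_hh_b, self.b_ih_b, self.b_hh_b, True
        )
        return concat([fwd, bwd], axis=-1)


class Conv3x3(Module):
    """3x3 convolution, stride 1, zero padding 1, on channels-last input.

    Implemented as nine shifted 1x1 projections, which keeps the whole
    operation inside the autograd primitives.
    """

    def __init__(self, in_channels: int, out_channels: int, rng):
        fan_in = in_channels * 9
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(3, 3, in_channels, out_channels))
        )
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, _ = x.shape
        padded = x.pad2d(1)
        out = None
        for di in range(3):
            for dj in range(3):
                patch = padded[:, di : di + H, dj : dj + W, :]
                term = patch @ self.weight[di, dj]
                out = term if out is None else out + term
        return out + self.bias
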