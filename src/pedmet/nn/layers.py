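"""Layers and optimizer built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module",
    "Dense",
    "Conv1D",
    "GRU",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "Adam",
]


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p.data = s.copy()


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1D(Module):
    """Valid 1-D convolution over the time axis of (B, T, C) inputs."""

    def __init__(self, n_channels: int, n_filters: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        limit = np.sqrt(6.0 / (kernel * n_channels + n_filters))
        self.w = Tensor(
            rng.uniform(-limit, limit, size=(kernel, n_channels, n_filters)), requires_grad=True
        )
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.w) + self.b


class GRU(Module):
    """Gated recurrent unit over (B, T, C); returns the final hidden state (B, H)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.wz = Dense(n_in, n_hidden, rng)
        self.uz = Dense(n_hidden, n_hidden, rng)
        self.wr = Dense(n_in, n_hidden, rng)
        self.ur = Dense(n_hidden, n_hidden, rng)
        self.wn = Dense(n_in, n_hidden, rng)
        self.un = Dense(n_hidden, n_hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        batch, steps = x.shape[0], x.shape[1]
        h = Tensor(np.zeros((batch, self.n_hidden)))
        for t in range(steps):
            xt = x[:, t, :]
            z = (self.wz(xt) + self.uz(h)).sigmoid()
            r = (self.wr(xt) + self.ur(h)).sigmoid()
            n = (self.wn(xt) + self.un(r * h)).tanh()
            h = (1.0 - z) * n + z * h
        return h


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training or self.rate <= 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (B, T, D)."""

    def __init__(self, dim: int, n_heads: int, head_size: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.head_size = head_size
        inner = n_heads * head_size
        self.wq = Dense(dim, inner, rng)
        self.wk = Dense(dim, inner, rng)
        self.wv = Dense(dim, inner, rng)
        self.wo = Dense(inner, dim, rng)

    def _split(self, x: Tensor, batch: int, steps: int) -> Tensor:
        return x.reshape(batch, steps, self.n_heads, self.head_size).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        batch, steps = x.shape[0], x.shape[1]
        q = self._split(self.wq(x), batch, steps)
        k = self._split(self.wk(x), batch, steps)
        v = self._split(self.wv(x), batch, steps)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_size))
        att = scores.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(batch, steps, self.n_heads * self.head_size)
        return self.wo(out)


class Adam:
    """Adam with a mutable learning rate (the decay schedule adjusts ``lr``)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
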