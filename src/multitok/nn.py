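"""Small neural-network building blocks on top of :mod:`multitok.autodiff`.

Parameters, linear layers, layer normalization, dropout and the Adam
optimizer — just enough to assemble transformer encoders and MLP heads.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def parameter(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    """Xavier-uniform initialized trainable tensor."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[1] if len(shape) > 1 else shape[0]
        scale = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def zeros_parameter(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def ones_parameter(*shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Linear:
    """Affine map ``x @ W + b`` applied to the last axis."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = parameter(rng, d_in, d_out)
        self.b = zeros_parameter(d_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class LayerNorm:
    """Normalize the last axis to zero mean / unit variance, then scale+shift."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = ones_parameter(d)
        self.bias = zeros_parameter(d)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gain + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.gain, self.bias]


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not train or rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer over an explicit parameter list."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
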