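"""Minimal reverse-mode layer stack for small convolutional networks.

The translator networks here are tiny (tens of thousands of parameters,
64x64 inputs), so they run on a compact, fully deterministic numpy engine:
each layer implements an explicit ``forward(x) -> (y, cache)`` and
``backward(dout, cache) -> dx`` pair, parameters accumulate gradients, and
Adam does the updates.  Functional caches (returned, not stored) allow the
same network to be applied several times inside one loss graph — which the
cycle-consistency objective requires.

Array convention: activations are ``(N, C, H, W)`` float32 (the
networks are small enough that single precision costs nothing in quality
and roughly halves the arithmetic time).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Upsample2x",
    "Sequential",
    "ResidualBlock",
    "Adam",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, dout: np.ndarray, cache):  # -> dx
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution, zero padding 'same' for stride 1, kernel k, stride s."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = 0.02
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self.weight = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = Param(np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray):
        k, s, p = self.kernel, self.stride, self.pad
        x_p = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(x_p, (k, k), axis=(2, 3))
        cols = windows[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        out = np.tensordot(cols, self.weight.data, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        out += self.bias.data[None, :, None, None]
        return out, (cols, x.shape)

    def backward(self, dout: np.ndarray, cache):
        cols, x_shape = cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x_shape
        ho, wo = dout.shape[2], dout.shape[3]
        self.weight.grad += np.tensordot(dout, cols, axes=([0, 2, 3], [0, 2, 3]))
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        dx_p = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                contrib = np.tensordot(dout, self.weight.data[:, :, i, j], axes=([1], [0]))
                dx_p[:, :, i : i + ho * s : s, j : j + wo * s : s] += contrib.transpose(0, 3, 1, 2)
        return dx_p[:, :, p : p + h, p : p + w]


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation with learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mu) * inv_std
        out = self.gamma.data[None, :, None, None] * x_hat + self.beta.data[None, :, None, None]
        return out, (x_hat, inv_std)

    def backward(self, dout: np.ndarray, cache):
        x_hat, inv_std = cache
        m = dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * x_hat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        # standard normalisation backward over the spatial axes
        term = (
            m * dxhat
            - dxhat.sum(axis=(2, 3), keepdims=True)
            - x_hat * (dxhat * x_hat).sum(axis=(2, 3), keepdims=True)
        )
        return inv_std / m * term


class ReLU(Layer):
    def forward(self, x: np.ndarray):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout: np.ndarray, cache):
        return dout * cache


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x: np.ndarray):
        mask = x > 0
        return np.where(mask, x, self.alpha * x), mask

    def backward(self, dout: np.ndarray, cache):
        return np.where(cache, dout, self.alpha * dout)


class Tanh(Layer):
    def forward(self, x: np.ndarray):
        y = np.tanh(x)
        return y, y

    def backward(self, dout: np.ndarray, cache):
        return dout * (1.0 - cache * cache)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward is 2x2 sum pooling."""

    def forward(self, x: np.ndarray):
        return x.repeat(2, axis=2).repeat(2, axis=3), None

    def backward(self, dout: np.ndarray, cache):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append(cache)
        return x, caches

    def backward(self, dout: np.ndarray, caches):
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dout = layer.backward(dout, cache)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())


class ResidualBlock(Layer):
    """conv-norm-relu-conv-norm with an identity skip."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.body = Sequential([
            Conv2d(channels, channels, 3, rng=rng),
            InstanceNorm2d(channels),
            ReLU(),
            Conv2d(channels, channels, 3, rng=rng),
            InstanceNorm2d(channels),
        ])

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray):
        y, caches = self.body.forward(x)
        return x + y, caches

    def backward(self, dout: np.ndarray, caches):
        return dout + self.body.backward(dout, caches)


class SkipConnection(Layer):
    """Global identity skip around an arbitrary body: y = x + body(x).

    With small-scale weight init the wrapped network starts as the
    identity map — the natural starting point for restoration-style
    translation where the output is a correction of the input.
    """

    def __init__(self, body: Layer):
        self.body = body

    def params(self) -> list[Param]:
        return self.body.params()

    def forward(self, x: np.ndarray):
        y, cache = self.body.forward(x)
        return x + y, cache

    def backward(self, dout: np.ndarray, cache):
        return dout + self.body.backward(dout, cache)


class Adam:
    """Adam with the bias-corrected update; one state slot per parameter."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
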