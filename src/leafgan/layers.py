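"""Neural-network layers and the RMSprop optimizer on top of the AD engine.

Layers are thin parameter containers with a ``forward`` method; networks are
plain sequences of layers.  Batches are NHWC float64, images scaled to
[-1, 1] at network input.
"""

from __future__ import annotations

import contextlib
import math
from typing import List, Sequence

import numpy as np

from .tensor import (Tensor, add, im2col, leaky_relu, matmul, maxpool2x2,
                     mul, pad2d, relu, reshape, softmax, tanh, tmean,
                     upsample_nearest)

__all__ = ["Layer", "Dense", "Conv2D", "BatchNorm", "ZeroPad", "UpSample",
           "MaxPool", "GlobalAvgPool", "Flatten", "Activation", "Reshape",
           "Sequential", "RMSprop", "same_pad", "frozen_batch_stats"]

_update_batch_stats = True


@contextlib.contextmanager
def frozen_batch_stats():
    """Use batch statistics without touching running averages.

    Needed when one network's update pass evaluates another network in
    training mode (e.g. the critic step generating fake images): the other
    network's buffers must stay bit-identical.
    """
    global _update_batch_stats
    prev = _update_batch_stats
    _update_batch_stats = False
    try:
        yield
    finally:
        _update_batch_stats = prev


def same_pad(n: int, ksize: int, stride: int) -> tuple:
    """'same' padding amounts (before, after) for one spatial dimension."""
    out = math.ceil(n / stride)
    total = max((out - 1) * stride + ksize - n, 0)
    return total // 2, total - total // 2


class Layer:
    def params(self) -> List[Tensor]:
        return []

    def forward(self, x: Tensor, train: bool = True) -> Tensor:  # pragma: no cover
        raise NotImplementedError

    def out_shape(self, shape: tuple) -> tuple:
        """Shape propagation for the architecture audit; NHWC sans batch."""
        raise NotImplementedError

    def state(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def load_state(self, st: dict) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = st[f"p{i}"]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.n_in, self.n_out = n_in, n_out

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if x.ndim > 2:
            x = reshape(x, (x.shape[0], -1))
        return add(matmul(x, self.w), self.b)

    def out_shape(self, shape):
        return (self.n_out,)


class Conv2D(Layer):
    """3×3 (or k×k) convolution with TensorFlow-style 'same' padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 ksize: int = 3, stride: int = 1):
        fan_in = ksize * ksize * c_in
        scale = math.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, scale, (fan_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.c_in, self.c_out, self.ksize, self.stride = c_in, c_out, ksize, stride

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        N, H, W, _ = x.shape
        ph = same_pad(H, self.ksize, self.stride)
        pw = same_pad(W, self.ksize, self.stride)
        if any(ph) or any(pw):
            x = pad2d(x, (ph, pw))
        cols = im2col(x, self.ksize, self.stride)
        _, OH, OW, K = cols.shape
        flat = matmul(reshape(cols, (N * OH * OW, K)), self.w)
        return reshape(add(flat, self.b), (N, OH, OW, self.c_out))

    def out_shape(self, shape):
        H, W, _ = shape
        return (math.ceil(H / self.stride), math.ceil(W / self.stride), self.c_out)


class BatchNorm(Layer):
    """Channel-wise batch normalization (running stats used at eval time)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = tmean(x, axis=axes, keepdims=True)
            cen = add(x, mul(Tensor(-1.0), mu))
            var = tmean(mul(cen, cen), axis=axes, keepdims=True)
            if _update_batch_stats:
                m = self.momentum
                self.run_mean = m * self.run_mean + (1 - m) * mu.data.ravel()
                self.run_var = m * self.run_var + (1 - m) * var.data.ravel()
        else:
            mu = Tensor(self.run_mean)
            var = Tensor(self.run_var)
            cen = add(x, mul(Tensor(-1.0), mu))
        xhat = mul(cen, pow_inv_sqrt(var, self.eps))
        return add(mul(xhat, self.gamma), self.beta)

    def out_shape(self, shape):
        return shape

    def state(self):
        st = super().state()
        st["run_mean"] = self.run_mean
        st["run_var"] = self.run_var
        return st

    def load_state(self, st):
        super().load_state(st)
        self.run_mean = np.array(st["run_mean"])
        self.run_var = np.array(st["run_var"])


def pow_inv_sqrt(var: Tensor, eps: float) -> Tensor:
    return (add(var, Tensor(eps))) ** -0.5


class ZeroPad(Layer):
    """Asymmetric zero padding, e.g. ((0,1),(0,1)) maps 32×32 to 33×33."""

    def __init__(self, pad: tuple):
        self.pad = pad

    def forward(self, x, train=True):
        return pad2d(x, self.pad)

    def out_shape(self, shape):
        H, W, C = shape
        (pt, pb), (pl, pr) = self.pad
        return (H + pt + pb, W + pl + pr, C)


class UpSample(Layer):
    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, train=True):
        return upsample_nearest(x, self.factor)

    def out_shape(self, shape):
        H, W, C = shape
        return (H * self.factor, W * self.factor, C)


class MaxPool(Layer):
    def forward(self, x, train=True):
        return maxpool2x2(x)

    def out_shape(self, shape):
        H, W, C = shape
        return (H // 2, W // 2, C)


class GlobalAvgPool(Layer):
    """Average pooling down to 1×1 spatial size."""

    def forward(self, x, train=True):
        return tmean(x, axis=(1, 2), keepdims=True)

    def out_shape(self, shape):
        return (1, 1, shape[2])


class Flatten(Layer):
    def forward(self, x, train=True):
        return reshape(x, (x.shape[0], -1))

    def out_shape(self, shape):
        return (int(np.prod(shape)),)


class Activation(Layer):
    _FNS = {
        "relu": relu,
        "leaky_relu": lambda x: leaky_relu(x, 0.2),
        "tanh": tanh,
        "softmax": softmax,
        "linear": lambda x: x,
    }

    def __init__(self, kind: str):
        if kind not in self._FNS:
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, train=True):
        return self._FNS[self.kind](x)

    def out_shape(self, shape):
        return shape


class Reshape(Layer):
    def __init__(self, shape: tuple):
        self.shape = tuple(shape)

    def forward(self, x, train=True):
        return reshape(x, (x.shape[0],) + self.shape)

    def out_shape(self, shape):
        return self.shape


class Sequential:
    """An ordered stack of layers sharing a parameter list."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> List[Tensor]:
        out = []
        for lyr in self.layers:
            out.extend(lyr.params())
        return out

    def forward(self, x: Tensor, train: bool = True) -> Tensor:
        for lyr in self.layers:
            x = lyr.forward(x, train=train)
        return x

    __call__ = forward

    def state(self) -> dict:
        return {str(i): lyr.state() for i, lyr in enumerate(self.layers)}

    def load_state(self, st: dict) -> None:
        # layers without parameters serialize to nothing
        for i, lyr in enumerate(self.layers):
            lyr.load_state(st.get(str(i), {}))


class RMSprop:
    """RMSprop with Keras semantics: cache ← ρ·cache + (1−ρ)·g²."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 rho: float = 0.9, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: Sequence[Tensor]) -> None:
        for p, c, g in zip(self.params, self.cache, grads):
            gd = g.data
            c *= self.rho
            c += (1.0 - self.rho) * gd * gd
            p.data -= self.lr * gd / (np.sqrt(c) + self.eps)

    def state(self) -> dict:
        return {str(i): np.array(c) for i, c in enumerate(self.cache)}

    def load_state(self, st: dict) -> None:
        for i, c in enumerate(self.cache):
            c[...] = st[str(i)]
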