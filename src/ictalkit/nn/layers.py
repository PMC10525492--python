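"""Neural layers built on the autodiff core: Conv2d, Dense, BatchNorm2d,
ConvLSTM2d, and the pooling/dropout wrappers. Parameters are Tensors with
``requires_grad=True``; each layer exposes ``params()`` for the optimizer."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Layer", "Conv2d", "Dense", "BatchNorm2d", "ConvLSTM2d"]


class Layer:
    def params(self) -> list[Tensor]:
        return []

    def state(self) -> dict:
        """Non-trainable state (running statistics) for serialization."""
        return {}


class Conv2d(Layer):
    """3x3 (by default) stride-1 convolution with symmetric padding 1."""

    def __init__(self, in_ch, out_ch, kernel=3, pad=1, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.pad = pad

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, pad=self.pad)

    def params(self):
        return [self.weight, self.bias]


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)

    def params(self):
        return [self.weight, self.bias]


class BatchNorm2d(Layer):
    def __init__(self, n_ch, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running = {"mean": np.zeros(n_ch), "var": np.ones(n_ch)}
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        return ad.batchnorm(
            x, self.gamma, self.beta, self.running, train, self.momentum, self.eps
        )

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return {"mean": self.running["mean"], "var": self.running["var"]}


class ConvLSTM2d(Layer):
    """Convolutional LSTM over a sequence of 2D feature maps.

    Gate pre-activations are a same-padded 3x3 convolution of the input frame
    plus one of the hidden state; the spatial size of the hidden state equals
    the input frame size. Forget-gate bias starts at 1.
    """

    def __init__(self, in_ch, filters, kernel=3, rng=None):
        rng = rng or np.random.default_rng()
        self.filters = filters
        fan_x = in_ch * kernel * kernel
        fan_h = filters * kernel * kernel
        self.wx = Tensor(
            rng.normal(0, np.sqrt(1.0 / fan_x), (4 * filters, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.wh = Tensor(
            rng.normal(0, np.sqrt(1.0 / fan_h), (4 * filters, filters, kernel, kernel)),
            requires_grad=True,
        )
        b = np.zeros(4 * filters)
        b[filters : 2 * filters] = 1.0  # forget gate
        self.bias = Tensor(b, requires_grad=True)
        self._zero_bias = Tensor(np.zeros(4 * filters))
        self.pad = kernel // 2

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = ad.add(
            ad.conv2d(x_t, self.wx, self.bias, pad=self.pad),
            ad.conv2d(h, self.wh, self._zero_bias, pad=self.pad),
        )
        f_ = self.filters
        i = ad.sigmoid(ad.slice_(z, (slice(None), slice(0, f_))))
        f = ad.sigmoid(ad.slice_(z, (slice(None), slice(f_, 2 * f_))))
        o = ad.sigmoid(ad.slice_(z, (slice(None), slice(2 * f_, 3 * f_))))
        g = ad.tanh(ad.slice_(z, (slice(None), slice(3 * f_, 4 * f_))))
        c_new = ad.add(ad.mul(f, c), ad.mul(i, g))
        h_new = ad.mul(o, ad.tanh(c_new))
        return h_new, c_new

    def forward_sequence(self, frames: list[Tensor], return_sequence: bool):
        n, _, hgt, wid = frames[0].shape
        h = Tensor(np.zeros((n, self.filters, hgt, wid)))
        c = Tensor(np.zeros((n, self.filters, hgt, wid)))
        outputs = []
        for x_t in frames:
            h, c = self.step(x_t, h, c)
            outputs.append(h)
        return outputs if return_sequence else [h]

    def params(self):
        return [self.wx, self.wh, self.bias]
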