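"""Parameterised layers (modules) over the autodiff engine."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, batchnorm, conv2d, relu

__all__ = ["Conv2d", "BatchNorm2d", "ConvUnit", "ConvBlock"]


class Conv2d:
    """k×k stride-1 convolution with bias, He-initialised from ``rng``.

    Kernel layout is (k, k, cin, cout) to match the NHWC engine; ``pad``
    defaults to "same" padding (k // 2).  ``zero_init`` starts the layer at
    an exact zero map (used for output heads so training begins from the
    maximum-entropy prediction).
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        pad: int | None = None,
        zero_init: bool = False,
    ):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((k, k, cin, cout))
        else:
            w = rng.normal(0.0, math.sqrt(2.0 / (cin * k * k)), size=(k, k, cin, cout))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return conv2d(x, self.w, self.b, pad=self.pad)

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]

    def buffers(self) -> list[np.ndarray]:
        return []


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            momentum=self.momentum, eps=self.eps, training=training,
        )

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class ConvUnit:
    """conv → (optional batch norm) → ReLU, the basic unit of every block."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 use_bn: bool = False):
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout) if use_bn else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        out = self.conv(x)
        if self.bn is not None:
            out = self.bn(out, training=training)
        return relu(out)

    def parameters(self) -> list[Tensor]:
        ps = self.conv.parameters()
        return ps + self.bn.parameters() if self.bn else ps

    def buffers(self) -> list[np.ndarray]:
        return self.bn.buffers() if self.bn else []


class ConvBlock:
    """Two 3×3 conv(+BN)+ReLU stages, the standard U-Net encoder/decoder block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 use_bn: bool = False):
        self.u1 = ConvUnit(cin, cout, 3, rng, use_bn)
        self.u2 = ConvUnit(cout, cout, 3, rng, use_bn)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        return self.u2(self.u1(x, training), training)

    def parameters(self) -> list[Tensor]:
        return self.u1.parameters() + self.u2.parameters()

    def buffers(self) -> list[np.ndarray]:
        return self.u1.buffers() + self.u2.buffers()

    @property
    def convs(self) -> list[Conv2d]:
        return [self.u1.conv, self.u2.conv]
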