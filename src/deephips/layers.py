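"""Trainable 3-D layers built on the autodiff core.

Layers operate on channel-first single-sample volumes ``(C, X, Y, Z)`` —
the training protocol uses a batch size of one, so no batch axis is
carried. Each layer exposes ``parameters()`` (trainable tensors),
``n_trainable``, and a ``forward(x, mode, rng)`` where ``mode`` is one of:

* ``"train"`` — batch statistics in normalization layers (updating the
  running averages), dropout active;
* ``"eval"``  — stored running statistics, dropout off;
* ``"ttbn"``  — batch statistics of the presented sample, running
  statistics left untouched, dropout off.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, channel_batchnorm, conv3d, max_pool3d, upsample3d

MODES = ("train", "eval", "ttbn")


class Layer:
    kind = "layer"

    def parameters(self):
        return []

    @property
    def n_trainable(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, x: Tensor, mode: str = "eval", rng=None) -> Tensor:
        raise NotImplementedError


class Conv3d(Layer):
    """Shape-preserving k×k×k convolution with bias (stride 1)."""

    kind = "conv3d"

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        # He initialization, appropriate for ReLU-coupled convolutions
        std = np.sqrt(2.0 / fan_in)
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels, kernel, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, mode="eval", rng=None):
        return conv3d(x, self.weight, self.bias)


class BatchNorm3d(Layer):
    """Per-channel normalization over the spatial axes of one sample.

    Trainable scale/shift; running mean/variance are non-trainable state
    (excluded from the trainable-parameter count) updated only in
    ``train`` mode.
    """

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, mode="eval", rng=None):
        c = x.shape[0]
        if c != self.channels:
            raise ValueError(f"BatchNorm expects {self.channels} channels, got {c}")
        sh = (c, 1, 1, 1)
        if mode in ("train", "ttbn"):
            out, mu, var = channel_batchnorm(x, self.gamma, self.beta, self.eps)
            if mode == "train":
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mu
                self.running_var = m * self.running_var + (1 - m) * var
            return out
        # eval: a constant per-channel affine map from the running statistics
        scale = (self.gamma.data / np.sqrt(self.running_var + self.eps)).reshape(sh)
        shift = (self.beta.data - self.running_mean * scale.reshape(c)).reshape(sh)
        return x * scale + shift


class Dropout(Layer):
    """Inverted dropout, active only in training mode."""

    kind = "dropout"

    def __init__(self, rate: float = 0.5):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, mode="eval", rng=None):
        if mode != "train" or self.rate == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask


class MaxPool3d(Layer):
    kind = "maxpool"

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, mode="eval", rng=None):
        return max_pool3d(x, self.factor)


class Upsample3d(Layer):
    """Parameter-free repeat upsampling."""

    kind = "upsample"

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x, mode="eval", rng=None):
        return upsample3d(x, self.factor)


class ConvBlock(Layer):
    """One convolution block: Conv3³ -> BN -> ReLU (default), or the
    BN -> Conv3³ -> ReLU ordering via ``order="bn_conv_relu"``."""

    kind = "convblock"

    def __init__(self, in_channels, out_channels, order="conv_bn_relu", rng=None):
        if order not in ("conv_bn_relu", "bn_conv_relu"):
            raise ValueError(f"unknown block order {order!r}")
        self.order = order
        self.conv = Conv3d(in_channels, out_channels, 3, rng=rng)
        self.bn = BatchNorm3d(out_channels if order == "conv_bn_relu" else in_channels)

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()

    def forward(self, x, mode="eval", rng=None):
        if self.order == "conv_bn_relu":
            return self.bn.forward(self.conv.forward(x), mode).relu()
        return self.conv.forward(self.bn.forward(x, mode)).relu()


def softmax_channels(x: Tensor) -> Tensor:
    """Per-voxel softmax over the channel axis (axis 0)."""
    shift = x - x.data.max(axis=0, keepdims=True)  # constant shift, grad-safe
    e = shift.exp()
    return e / e.sum(axis=0, keepdims=True)


class SoftmaxHead(Layer):
    """Per-voxel classification head: optional BN, 1×1×1 conv, softmax."""

    kind = "head"

    def __init__(self, in_channels, n_classes, kernel=1, with_bn=False, rng=None):
        self.bn = BatchNorm3d(in_channels) if with_bn else None
        self.conv = Conv3d(in_channels, n_classes, kernel, rng=rng)

    def parameters(self):
        ps = self.conv.parameters()
        if self.bn is not None:
            ps = self.bn.parameters() + ps
        return ps

    def forward(self, x, mode="eval", rng=None):
        if self.bn is not None:
            x = self.bn.forward(x, mode)
        return softmax_channels(self.conv.forward(x))
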