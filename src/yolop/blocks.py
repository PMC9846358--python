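"""Reusable network building blocks of the pear detector.

The backbone is assembled from three families of units:

* **CBH** — plain convolution + batch norm + Hard-Swish, used in the stem and
  throughout the neck (the Hard-Swish counterpart of the CBS unit).
* **Shuffle blocks** — ShuffleNetV2-style split / depthwise / concat /
  channel-shuffle units for the shallow and middle stages.
* **Inverted shuffle blocks** — the same split-concat-shuffle skeleton, but
  the processing branch is a *reducing* bottleneck: a pointwise convolution
  first shrinks the channel width by the bottleneck ratio ``t`` (< 1), a
  depthwise convolution filters spatially, and a linear pointwise convolution
  expands back.  Low-dimensional projections keep the deep-stage features of
  small fruit from being washed out, and the final projection of every branch
  is deliberately linear (no activation) so that the low-dimensional output
  is not clipped.

`CBAM` (channel-then-spatial attention with a residual add) and `SPPF`
(chained 5x5 max-pools) complete the set.

All blocks are pure functions of their input given fixed weights and never
modify the input in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as A


class ConfigError(ValueError):
    """Raised when a block configuration violates its structural invariants."""


def hard_swish(x):
    """Hard-Swish on plain numbers / arrays: x * relu6(x + 3) / 6.

    Bounded below by -0.375 and equal to the identity for x >= 3.  For
    autodiff tensors use :func:`yolop.nn.hard_swish`.
    """
    x = np.asarray(x, dtype=np.float64)
    out = x * np.clip(x + 3.0, 0.0, 6.0) / 6.0
    return out if out.ndim else float(out)


def channel_shuffle(x, groups: int):
    """Interleave channel groups: reshape to (g, C/g), transpose, flatten.

    Output channel ``j*g + i`` is input channel ``i*(C/g) + j``.  Accepts a
    batched autodiff tensor (N,C,H,W) or a bare (C,H,W) array.
    """
    if groups < 1:
        raise ConfigError("groups must be a positive integer")
    if isinstance(x, Tensor):
        n, c, h, w = x.shape
        if c % groups:
            raise ConfigError(f"channels {c} not divisible by groups {groups}")
        return (x.reshape(n, groups, c // groups, h, w)
                 .transpose(0, 2, 1, 3, 4)
                 .reshape(n, c, h, w))
    x = np.asarray(x)
    c = x.shape[0]
    if c % groups:
        raise ConfigError(f"channels {c} not divisible by groups {groups}")
    return (x.reshape(groups, c // groups, *x.shape[1:])
             .swapaxes(0, 1)
             .reshape(x.shape))


@dataclass
class BlockConfig:
    """Structural parameters of one block.

    stride 1 requires in == out channels (the pass-through half must match);
    stride 2 doubles the width.  ``expansion`` is the inverted-bottleneck
    ratio t (< 1: reduce first, expand back).
    """

    in_channels: int
    out_channels: int
    stride: int = 1
    kernel: int = 3
    expansion: float = 0.5
    groups: int = 2

    def __post_init__(self):
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ConfigError("channel counts must be positive")
        if self.stride not in (1, 2):
            raise ConfigError("stride must be 1 or 2")
        if self.kernel % 2 == 0:
            raise ConfigError("kernel size must be odd")
        if self.expansion <= 0:
            raise ConfigError("expansion ratio must be positive")
        if self.stride == 1 and self.in_channels != self.out_channels:
            raise ConfigError("stride-1 blocks require in == out channels")
        if self.stride == 2 and self.out_channels != 2 * self.in_channels:
            raise ConfigError("stride-2 blocks require out == 2 * in channels")
        if self.stride == 1 and self.in_channels % 2:
            raise ConfigError("stride-1 blocks require an even channel count")


_ACTS = {"hardswish": nn.HardSwish, "silu": nn.SiLU, "relu": nn.ReLU,
         None: nn.Identity, "linear": nn.Identity}


class ConvBnAct(nn.Module):
    """Conv -> BatchNorm -> activation, 'same' padding (k // 2)."""

    def __init__(self, c1, c2, k=1, s=1, groups=1, act="hardswish"):
        super().__init__()
        if k % 2 == 0:
            raise ConfigError("kernel size must be odd")
        self.conv = nn.Conv2d(c1, c2, k, s, k // 2, groups=groups)
        self.bn = nn.BatchNorm2d(c2)
        self.act = _ACTS[act]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class CBH(ConvBnAct):
    """Conv + Batch Norm + Hard-Swish."""

    def __init__(self, c1, c2, k=1, s=1, groups=1):
        super().__init__(c1, c2, k, s, groups, act="hardswish")


def _dw(c, s):
    """3x3 depthwise conv + BN, no nonlinearity (ShuffleNet convention)."""
    return nn.Sequential(nn.Conv2d(c, c, 3, s, 1, groups=c), nn.BatchNorm2d(c))


class ShuffleBlock(nn.Module):
    """ShuffleNetV2 unit.

    stride 1: channel split into halves; one half goes through
    1x1 conv -> 3x3 depthwise -> 1x1 conv; the untouched half is concatenated
    back and the result channel-shuffled (groups 2).
    stride 2: no split; a second branch (depthwise stride 2 + 1x1 conv) is
    added so the output doubles the channels and halves the spatial size.
    """

    def __init__(self, channels: int, stride: int = 1, act="hardswish"):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigError("stride must be 1 or 2")
        if stride == 1 and channels % 2:
            raise ConfigError("stride-1 shuffle block needs even channels")
        self.stride = stride
        self.channels = channels
        c = channels // 2 if stride == 1 else channels
        self.branch_main = nn.Sequential(
            ConvBnAct(c, c, 1, 1, act=act),
            _dw(c, stride),
            ConvBnAct(c, c, 1, 1, act=act),
        )
        if stride == 2:
            self.branch_proj = nn.Sequential(
                _dw(channels, 2),
                ConvBnAct(channels, channels, 1, 1, act=act),
            )

    @property
    def out_channels(self):
        return self.channels * (1 if self.stride == 1 else 2)

    def forward(self, x):
        if self.stride == 1:
            c = self.channels // 2
            keep, work = x[:, :c], x[:, c:]
            out = A.concat([keep, self.branch_main(work)], axis=1)
        else:
            out = A.concat([self.branch_proj(x), self.branch_main(x)], axis=1)
        return channel_shuffle(out, 2)


class InvertedShuffleBlock(nn.Module):
    """Shuffle unit whose processing branch is a reducing bottleneck.

    The branch projects the width down by ``expansion`` (t < 1), filters with
    a 3x3 depthwise convolution, then expands back with a *linear* pointwise
    convolution; in the stride-2 variant the second branch's projection
    convolution is linear as well.
    """

    def __init__(self, channels: int, stride: int = 1, expansion: float = 0.5,
                 act="hardswish"):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigError("stride must be 1 or 2")
        if stride == 1 and channels % 2:
            raise ConfigError("stride-1 inverted shuffle block needs even channels")
        if expansion <= 0:
            raise ConfigError("bottleneck ratio must be positive")
        self.stride = stride
        self.channels = channels
        self.expansion = expansion
        c = channels // 2 if stride == 1 else channels
        mid = max(1, round(c * expansion))
        self.branch_main = nn.Sequential(
            ConvBnAct(c, mid, 1, 1, act=act),
            _dw(mid, stride),
            ConvBnAct(mid, c, 1, 1, act="linear"),   # linear projection
        )
        if stride == 2:
            self.branch_proj = nn.Sequential(
                _dw(channels, 2),
                ConvBnAct(channels, channels, 1, 1, act="linear"),
            )

    @property
    def out_channels(self):
        return self.channels * (1 if self.stride == 1 else 2)

    def forward(self, x):
        if self.stride == 1:
            c = self.channels // 2
            keep, work = x[:, :c], x[:, c:]
            out = A.concat([keep, self.branch_main(work)], axis=1)
        else:
            out = A.concat([self.branch_proj(x), self.branch_main(x)], axis=1)
        return channel_shuffle(out, 2)


class CBAM(nn.Module):
    """Convolutional block attention: channel stage, spatial stage, residual.

    Channel stage (CAM): global average and max pooling over space feed one
    shared two-layer perceptron (reduction ``r``); the summed outputs pass a
    sigmoid and reweight the channels.  Spatial stage (SAM): mean and max over
    channels form a 2-plane map, a 7x7 convolution and sigmoid give a spatial
    mask.  The refined map is added back onto the input.
    """

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)
        self.spatial_conv = nn.Conv2d(2, 1, spatial_kernel, 1,
                                      spatial_kernel // 2, bias=False)
        self.channels = channels

    def forward(self, x):
        n, c, h, w = x.shape
        gap = x.mean(axis=(2, 3))                    # (N, C)
        gmp = x.reshape(n, c, h * w).amax(axis=2)    # (N, C)
        mlp = self.fc2(A.relu(self.fc1(gap))) + self.fc2(A.relu(self.fc1(gmp)))
        ch_w = A.sigmoid(mlp).reshape(n, c, 1, 1)
        refined = x * ch_w
        sp_mean = refined.mean(axis=1, keepdims=True)
        sp_max = refined.amax(axis=1, keepdims=True)
        mask = A.sigmoid(self.spatial_conv(A.concat([sp_mean, sp_max], axis=1)))
        return x + refined * mask


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 stride-1 max-pools.

    The 1x1 entry conv halves the width; the four pyramid stages are
    concatenated (4 * C/2 channels) and fused by a 1x1 exit conv.
    """

    def __init__(self, c1, c2, k=5, act="hardswish"):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv2 = ConvBnAct(c_ * 4, c2, 1, 1, act=act)
        self.pool = nn.MaxPool2d(k, 1, k // 2)

    def forward(self, x):
        x = self.cv1(x)
        p1 = self.pool(x)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.cv2(A.concat([x, p1, p2, p3], axis=1))
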