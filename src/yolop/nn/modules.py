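"""Layer modules on top of the autodiff tape.

Follows the torch-style Module idiom: parameters are discovered recursively,
``train()``/``eval()`` toggle batch-norm behaviour, and modules are callable.
Weight initialisation draws from a module-level generator so that a whole
model build is reproducible from one call to :func:`seed_all`.
"""

from __future__ import annotations

import math

import numpy as np

from . import autograd as A
from .autograd import Tensor
from .profile import record_conv

_rng = np.random.default_rng(0)


def seed_all(seed: int):
    """Reset the initialisation stream; call before building a model."""
    global _rng
    _rng = np.random.default_rng(seed)


class Parameter(Tensor):
    """Learnable tensor; stored float32 regardless of the init dtype."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32),
                         requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = list(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Cross-correlation layer; ``padding=None`` means 'same' (k // 2)."""

    def __init__(self, in_channels, out_channels, kernel=1, stride=1,
                 padding=None, groups=1, bias=False):
        super().__init__()
        if kernel % 2 == 0 and padding is None:
            padding = (kernel - 1) // 2
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = int(kernel)
        self.stride = int(stride)
        self.padding = kernel // 2 if padding is None else int(padding)
        self.groups = int(groups)
        fan_in = (in_channels // groups) * kernel * kernel
        bound = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(_rng.normal(
            0.0, bound, (out_channels, in_channels // groups, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        out = A.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                       self.groups)
        record_conv(self, out.shape)
        return out


class BatchNorm2d(Module):
    """YOLO-flavoured defaults: eps 1e-3, momentum 0.03."""

    def __init__(self, channels, eps=1e-3, momentum=0.03):
        super().__init__()
        self.channels = int(channels)
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return A.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum,
                              self.eps)


class HardSwish(Module):
    def forward(self, x):
        return A.hard_swish(x)


class SiLU(Module):
    def forward(self, x):
        return A.silu(x)


class ReLU(Module):
    def forward(self, x):
        return A.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return A.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel, stride=1, padding=None):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding

    def forward(self, x):
        return A.max_pool2d(x, self.kernel, self.stride, self.padding)


class UpsampleNearest2x(Module):
    def forward(self, x):
        return A.upsample_nearest2x(x)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = math.sqrt(2.0 / in_features)
        self.weight = Parameter(_rng.normal(0.0, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
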