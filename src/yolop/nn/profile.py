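"""Recording of convolution shapes during a forward pass.

Used by the FLOPs counter: a model is run once inside :func:`profile` and
every Conv2d appends its resolved (C_in, C_out, k, stride, groups, OH, OW).
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass

_ACTIVE: list | None = None


@dataclass(frozen=True)
class ConvRecord:
    in_channels: int
    out_channels: int
    kernel: int
    stride: int
    groups: int
    out_h: int
    out_w: int

    def macs(self) -> int:
        """Multiply-accumulate ops: L^2 * K^2 * C_out * (C_in / groups)."""
        return (self.out_h * self.out_w * self.kernel ** 2
                * self.out_channels * (self.in_channels // self.groups))


@contextlib.contextmanager
def profile():
    global _ACTIVE
    prev, _ACTIVE = _ACTIVE, []
    try:
        yield _ACTIVE
    finally:
        _ACTIVE = prev


def record_conv(conv, out_shape):
    if _ACTIVE is not None:
        _ACTIVE.append(ConvRecord(conv.in_channels, conv.out_channels,
                                  conv.kernel, conv.stride, conv.groups,
                                  int(out_shape[-2]), int(out_shape[-1])))
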