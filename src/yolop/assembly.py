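"""Assembly of the pear detector and its reference/ablation variants.

``build_yolop`` constructs the full detector: a reconstructed backbone
(stem convs, shuffle-block stages, inverted-shuffle deep stage, SPPF) with
CBAM attention at the end of stages 2-4, a YOLOv5s-style FPN+PAN neck, and a
single-class anchor head (5 outputs per anchor: box 4 + objectness, no class
channel).  ``build_variant`` provides the CSP-DarkNet53 baseline and the
ablation ladder T1-T4.

The stage repeat counts and the bottleneck ratio of the inverted shuffle
blocks are not free: they are frozen by ``scripts/calibrate.py`` so that the
multiply-add count and the half-precision weight-file size of the assembled
models land on the published accounting (10.1 GFLOPs / 8.3 MB for the
detector, 15.9 GFLOPs / 13.7 MB for the baseline).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .blocks import (CBAM, SPPF, ConfigError, ConvBnAct, InvertedShuffleBlock,
                     ShuffleBlock)
from .nn import autograd as A
from .nn.profile import ConvRecord, profile

# Calibrated, frozen architecture constants (see scripts/calibrate.py).
DEFAULT_STAGE_REPEATS = (11, 9, 1)
DEFAULT_EXPANSION = 0.5
DEFAULT_CBAM_REDUCTION = 16

# Default anchor priors (w, h) in pixels at 640 input, per scale.
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),        # P3 / stride 8  (small)
    ((30, 61), (62, 45), (59, 119)),       # P4 / stride 16 (medium)
    ((116, 90), (156, 198), (373, 326)),   # P5 / stride 32 (large)
)

VARIANTS = ("yolop", "yolov5s", "T1", "T2", "T3", "T4")
OUTPUTS_PER_ANCHOR = 5  # cx, cy, w, h, objectness — no class channel
STRIDES = (8, 16, 32)


@dataclass
class ArchSpec:
    """Declarative description of a detector variant."""

    variant: str = "yolop"
    width: float = 1.0                      # channel multiplier (tiny presets)
    stage_repeats: tuple = DEFAULT_STAGE_REPEATS
    expansion: float = DEFAULT_EXPANSION
    cbam: bool = True
    cbam_reduction: int = DEFAULT_CBAM_REDUCTION
    act: str = "hardswish"
    anchors: tuple = DEFAULT_ANCHORS
    seed: int = 0

    def channels(self):
        base = (32, 64, 128, 256, 512)
        return tuple(max(8, int(round(c * self.width / 8)) * 8) if self.width != 1.0
                     else c for c in base)


@dataclass
class ModelSummary:
    parameter_count: int
    flops: int                  # multiply + add ops over conv layers
    serialized_megabytes: float
    input_size: int = 640

    @property
    def gflops(self) -> float:
        return self.flops / 1e9


# ---------------------------------------------------------------------------
# YOLOv5-style fusion units (baseline backbone + shared neck)
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, e=0.5, act="silu"):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv2 = ConvBnAct(c_, c2, 3, 1, act=act)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(nn.Module):
    """Cross-stage-partial fusion block (two parallel 1x1 paths)."""

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, act="silu"):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv2 = ConvBnAct(c1, c_, 1, 1, act=act)
        self.cv3 = ConvBnAct(2 * c_, c2, 1, 1, act=act)
        self.m = nn.Sequential(*[Bottleneck(c_, c_, shortcut, 1.0, act)
                                 for _ in range(n)])

    def forward(self, x):
        return self.cv3(A.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class Neck(nn.Module):
    """FPN + PAN over taps (C3 at stride 8, C4 at 16, C5 at 32)."""

    def __init__(self, c3, c4, c5, act="hardswish"):
        super().__init__()
        self.lat5 = ConvBnAct(c5, c4, 1, 1, act=act)
        self.fuse4 = C3(2 * c4, c4, 1, False, act=act)
        self.lat4 = ConvBnAct(c4, c3, 1, 1, act=act)
        self.fuse3 = C3(2 * c3, c3, 1, False, act=act)
        self.down3 = ConvBnAct(c3, c3, 3, 2, act=act)
        self.fuse4b = C3(2 * c3, c4, 1, False, act=act)
        self.down4 = ConvBnAct(c4, c4, 3, 2, act=act)
        self.fuse5b = C3(2 * c4, c5, 1, False, act=act)
        self.up = nn.UpsampleNearest2x()

    def forward(self, p3, p4, p5):
        x5 = self.lat5(p5)
        x4 = self.fuse4(A.concat([self.up(x5), p4], axis=1))
        x4l = self.lat4(x4)
        out3 = self.fuse3(A.concat([self.up(x4l), p3], axis=1))
        out4 = self.fuse4b(A.concat([self.down3(out3), x4l], axis=1))
        out5 = self.fuse5b(A.concat([self.down4(out4), x5], axis=1))
        return out3, out4, out5


class Head(nn.Module):
    """One 1x1 conv per scale emitting anchors * 5 raw channels."""

    def __init__(self, channels, n_anchors=3):
        super().__init__()
        self.convs = [nn.Conv2d(c, n_anchors * OUTPUTS_PER_ANCHOR, 1, bias=True)
                      for c in channels]
        # start objectness strongly negative so early confidences are low
        for conv in self.convs:
            bias = conv.bias.data.reshape(n_anchors, OUTPUTS_PER_ANCHOR)
            bias[:, 4] = -4.5

    def forward(self, feats):
        return [conv(f) for conv, f in zip(self.convs, feats)]


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class ShuffleBackbone(nn.Module):
    """The reconstructed backbone: stem convs, shuffle stages, SPPF.

    ``kinds`` selects the block family per downsampling stage; stage 1 may be
    plain convs ("conv") or a block stage (ablation variants T1/T2).
    """

    def __init__(self, spec: ArchSpec, kinds):
        super().__init__()
        c1, c2, c3, c4, c5 = spec.channels()
        act = spec.act
        t = spec.expansion
        n2, n3, n4 = spec.stage_repeats
        n1 = n2  # stage-1 repeat count for block-stage ablations

        def make(kind, channels, stride):
            if kind == "shuffle":
                return ShuffleBlock(channels, stride, act=act)
            return InvertedShuffleBlock(channels, stride, t, act=act)

        def stage(kind, cin, n):
            mods = [make(kind, cin, 2)]
            mods += [make(kind, 2 * cin, 1) for _ in range(n)]
            return nn.Sequential(*mods)

        if kinds[0] == "conv":
            self.stem = nn.Sequential(ConvBnAct(3, c1, 3, 2, act=act),
                                      ConvBnAct(c1, c2, 3, 2, act=act))
        else:
            self.stem = nn.Sequential(ConvBnAct(3, c1, 3, 2, act=act),
                                      stage(kinds[0], c1, n1))
        self.stage2 = stage(kinds[1], c2, n2)
        self.stage3 = stage(kinds[2], c3, n3)
        self.stage4 = stage(kinds[3], c4, n4)
        self.sppf = SPPF(c5, c5, act=act)
        if spec.cbam:
            self.cbam2 = CBAM(c3, spec.cbam_reduction)
            self.cbam3 = CBAM(c4, spec.cbam_reduction)
            self.cbam4 = CBAM(c5, spec.cbam_reduction)
        else:
            self.cbam2 = self.cbam3 = self.cbam4 = nn.Identity()
        self.out_channels = (c3, c4, c5)

    def forward(self, x):
        x = self.stem(x)
        p3 = self.cbam2(self.stage2(x))
        p4 = self.cbam3(self.stage3(p3))
        p5 = self.sppf(self.cbam4(self.stage4(p4)))
        return p3, p4, p5


class CSPBackbone(nn.Module):
    """CSP-DarkNet53 at small width/depth (the YOLOv5s reference backbone)."""

    def __init__(self, spec: ArchSpec):
        super().__init__()
        c1, c2, c3, c4, c5 = spec.channels()
        act = spec.act
        # 6x6 stride-2 stem conv (the release-6 replacement of the focus layer)
        self.stem = nn.Sequential(nn.Conv2d(3, c1, 6, 2, 2),
                                  nn.BatchNorm2d(c1),
                                  {"silu": nn.SiLU, "hardswish": nn.HardSwish}[act]())
        self.stage1 = nn.Sequential(ConvBnAct(c1, c2, 3, 2, act=act),
                                    C3(c2, c2, 1, act=act))
        self.stage2 = nn.Sequential(ConvBnAct(c2, c3, 3, 2, act=act),
                                    C3(c3, c3, 2, act=act))
        self.stage3 = nn.Sequential(ConvBnAct(c3, c4, 3, 2, act=act),
                                    C3(c4, c4, 3, act=act))
        self.stage4 = nn.Sequential(ConvBnAct(c4, c5, 3, 2, act=act),
                                    C3(c5, c5, 1, act=act))
        self.sppf = SPPF(c5, c5, act=act)
        self.out_channels = (c3, c4, c5)

    def forward(self, x):
        x = self.stage1(self.stem(x))
        p3 = self.stage2(x)
        p4 = self.stage3(p3)
        p5 = self.sppf(self.stage4(p4))
        return p3, p4, p5


class Detector(nn.Module):
    """Backbone + FPN/PAN neck + single-class anchor head."""

    def __init__(self, spec: ArchSpec, backbone: nn.Module):
        super().__init__()
        self.spec = spec
        self.backbone = backbone
        c3, c4, c5 = backbone.out_channels
        self.neck = Neck(c3, c4, c5, act=spec.act)
        self.head = Head((c3, c4, c5))

    def forward(self, x):
        if isinstance(x, np.ndarray):
            x = nn.Tensor(x)
        h, w = x.shape[-2:]
        if h % 32 or w % 32:
            raise ConfigError("input size must be divisible by 32")
        return self.head(self.neck(*self.backbone(x)))

    # -- accounting ----------------------------------------------------
    def summary(self, input_size: int = 640) -> ModelSummary:
        return ModelSummary(
            parameter_count=self.num_parameters(),
            flops=count_flops(self, input_size),
            serialized_megabytes=serialized_volume(self),
            input_size=input_size,
        )


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_yolop(input_size: int = 640, spec: ArchSpec | None = None) -> Detector:
    """Assemble the full detector with the frozen default configuration."""
    if input_size % 32:
        raise ConfigError("input size must be divisible by 32")
    spec = spec or ArchSpec(variant="yolop")
    nn.seed_all(spec.seed)
    kinds = ("conv", "shuffle", "shuffle", "inverted")
    return Detector(spec, ShuffleBackbone(spec, kinds))


def build_variant(name: str, spec: ArchSpec | None = None) -> Detector:
    """Build the baseline or an ablation variant.

    yolov5s — CSP-DarkNet53 + PANet, SiLU; T1 — all four backbone stages as
    shuffle blocks (SiLU, no CBAM); T2 — all four as inverted shuffle blocks;
    T3 — the mixed backbone with SiLU and no CBAM; T4 — T3 with Hard-Swish;
    yolop — T4 plus CBAM.
    """
    if name not in VARIANTS:
        raise ConfigError(f"unknown variant {name!r}; valid: {', '.join(VARIANTS)}")
    base = spec or ArchSpec()
    if name == "yolop":
        return build_yolop(spec=base)
    kinds = {
        "T1": ("shuffle", "shuffle", "shuffle", "shuffle"),
        "T2": ("inverted", "inverted", "inverted", "inverted"),
        "T3": ("conv", "shuffle", "shuffle", "inverted"),
        "T4": ("conv", "shuffle", "shuffle", "inverted"),
    }
    act = {"T4": "hardswish"}.get(name, "silu")
    v = ArchSpec(variant=name, width=base.width, stage_repeats=base.stage_repeats,
                 expansion=base.expansion, cbam=False, act=act,
                 anchors=base.anchors, seed=base.seed)
    nn.seed_all(v.seed)
    if name == "yolov5s":
        return Detector(v, CSPBackbone(v))
    return Detector(v, ShuffleBackbone(v, kinds[name]))


def tiny_spec(seed: int = 0) -> ArchSpec:
    """Desk-scale preset: quarter width, shallow stages, for smoke training."""
    return ArchSpec(variant="yolop", width=0.25, stage_repeats=(1, 2, 1),
                    cbam=True, cbam_reduction=4, seed=seed)


# ---------------------------------------------------------------------------
# FLOPs / volume accounting
# ---------------------------------------------------------------------------

_TRACE_SIZE = 64  # smallest input with a valid stride-32 map; shapes scale


def trace_convs(model: Detector, input_size: int = 640) -> list[ConvRecord]:
    """Resolved per-conv shapes at ``input_size``.

    The model runs once at a small reference size; every spatial extent in
    this architecture is input_size / stride, so records rescale exactly.
    """
    if input_size % 32:
        raise ConfigError("input size must be divisible by 32")
    was_training = model.training
    model.eval()
    with A.no_grad(), profile() as records:
        model(np.zeros((1, 3, _TRACE_SIZE, _TRACE_SIZE), dtype=np.float32))
    model.train(was_training)
    s = input_size // _TRACE_SIZE
    if input_size % _TRACE_SIZE:
        # non-multiple sizes: trace at the true size instead
        model.eval()
        with A.no_grad(), profile() as records:
            model(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
        model.train(was_training)
        s = 1
    return [ConvRecord(r.in_channels, r.out_channels, r.kernel, r.stride,
                       r.groups, r.out_h * s, r.out_w * s) for r in records]


def count_macs(model: Detector, input_size: int = 640) -> int:
    """Sum over conv layers of L^2 * K^2 * C_out * C_in (per-group C_in)."""
    return sum(r.macs() for r in trace_convs(model, input_size))


def count_flops(model: Detector, input_size: int = 640) -> int:
    """Total floating-point operations (multiplications + additions).

    Each multiply-accumulate counts as two ops, the convention of standard
    network profilers and of the published accounting this package
    reproduces.  Non-convolutional layers contribute zero.
    """
    return 2 * count_macs(model, input_size)


# -- weight archive ---------------------------------------------------------

_MAGIC = b"YLPW"


def save_weights(model: nn.Module, path, dtype: str = "<f2") -> int:
    """Serialize parameters + batch-norm statistics (default float16).

    Single-file archive: magic, version byte, a JSON manifest of entry names
    and shapes, then the raw little-endian payload.  Returns the file size in
    bytes.  Training checkpoints use ``dtype='<f4'`` for lossless resume.
    """
    entries, blobs = [], []
    for name, p in model.named_parameters():
        entries.append({"name": name, "shape": list(p.data.shape), "kind": "param"})
        blobs.append(p.data.astype(dtype).tobytes())
    for name, b in model.named_buffers():
        entries.append({"name": name, "shape": list(b.shape), "kind": "buffer"})
        blobs.append(b.astype(dtype).tobytes())
    dtype_name = {"<f2": "float16", "<f4": "float32"}[dtype]
    header = json.dumps({"dtype": dtype_name, "entries": entries},
                        separators=(",", ":")).encode()
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BI", 1, len(header)))
        fh.write(header)
        for blob in blobs:
            fh.write(blob)
    return path.stat().st_size


def load_weights(model: nn.Module, path):
    """Restore an archive written by :func:`save_weights`; validates shapes."""
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError("not a weight archive")
        _, hlen = struct.unpack("<BI", fh.read(5))
        header = json.loads(fh.read(hlen))
        dt = {"float16": "<f2", "float32": "<f4"}.get(header["dtype"])
        if dt is None:
            raise ValueError("unsupported payload dtype")
        itemsize = 2 if dt == "<f2" else 4
        params = dict(model.named_parameters())
        buffers = dict(model.named_buffers())
        for entry in header["entries"]:
            shape = tuple(entry["shape"])
            n = int(np.prod(shape)) if shape else 1
            raw = np.frombuffer(fh.read(itemsize * n), dtype=dt).reshape(shape)
            target = params if entry["kind"] == "param" else buffers
            if entry["name"] not in target:
                raise ValueError(f"unknown entry {entry['name']!r}")
            dest = target[entry["name"]]
            dest_arr = dest.data if isinstance(dest, nn.Tensor) else dest
            if dest_arr.shape != shape:
                raise ValueError(f"shape mismatch for {entry['name']!r}")
            dest_arr[...] = raw.astype(np.float32)
    return model


def serialized_volume(model: nn.Module, path=None) -> float:
    """Weight-file size in binary megabytes (MiB = 2^20 bytes).

    Writes the half-precision archive (to a temporary file unless ``path``
    is given) and measures it; nothing is estimated.
    """
    import tempfile

    if path is not None:
        nbytes = save_weights(model, path)
    else:
        with tempfile.NamedTemporaryFile(suffix=".ylpw") as fh:
            nbytes = save_weights(model, fh.name)
    return nbytes / 2 ** 20
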