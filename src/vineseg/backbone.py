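"""ResNet50-FPN-ED feature extractor.

The backbone follows the classic residual-bottleneck + feature-pyramid
recipe with two modifications, which are the heart of this package:

* **ECA** — each stage output C2..C5 passes an Efficient Channel Attention
  gate before the lateral 1x1 reduction: global average pooling, a 1-D
  convolution of adaptively chosen odd width k across the channel axis, a
  sigmoid, and channel-wise rescaling.  k is derived from the channel count
  as psi(C) = |log2(C)/gamma + b/gamma|_odd with gamma=2, b=1.
* **DUC** — the top-down pathway upsamples with Dense Upsampling Convolution
  (3x3 convolution to C*r^2 channels followed by the periodic sub-pixel
  rearrangement, r=2) instead of nearest-neighbour interpolation, so the
  upsampler is learnable and recovers detail for the mask task.

Pyramid contract (input sides divisible by 64): P2..P6 all carry the same
channel width with strides 4, 8, 16, 32, 64; P6 is a stride-2 max-pool of
the post-anti-aliasing P5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ECAConfig", "DUCConfig", "FeaturePyramid", "eca_kernel_size",
           "ECAModule", "DUC", "Bottleneck", "ResNetStages", "FPNED",
           "BackboneED"]

STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32, "P6": 64}


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive odd 1-D kernel width psi(C) for the channel-attention gate.

    t = |log2(C)/gamma + b/gamma|; the odd number 'similar to' t is resolved
    as int(t), bumped up by one if even (the upstream ECA convention).
    """
    if channels < 1:
        raise ValueError(f"channel count must be >= 1, got {channels}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    t = abs(np.log2(channels) / gamma + b / gamma)
    k = int(t)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


@dataclass
class ECAConfig:
    channels: int
    gamma: float = 2.0
    b: float = 1.0
    kernel_size: Optional[int] = None      # derived from channels unless set

    def __post_init__(self):
        if self.kernel_size is None:
            self.kernel_size = eca_kernel_size(self.channels, self.gamma, self.b)
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >=1, got {self.kernel_size}")


@dataclass
class DUCConfig:
    channels: int
    ratio: int = 2

    def __post_init__(self):
        if self.ratio < 1:
            raise ValueError("upscale ratio must be >= 1")

    @property
    def intermediate_channels(self) -> int:
        return self.channels * self.ratio * self.ratio


@dataclass
class FeaturePyramid:
    """P2..P6 maps (N, C, H, W) with their strides relative to the input."""

    levels: dict                      # name -> Tensor
    strides: dict = field(default_factory=lambda: dict(STRIDES))
    channels: int = 256

    def __getitem__(self, name: str) -> Tensor:
        return self.levels[name]

    @property
    def names(self):
        return list(self.levels)

    def shape_summary(self) -> dict:
        return {k: tuple(v.shape) for k, v in self.levels.items()}


class ECAModule(nn.Module):
    """Pure channel gate: k learnable weights, no bias, sigmoid output."""

    def __init__(self, config: ECAConfig, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        k = config.kernel_size
        self.kernel = nn.Parameter(rng.normal(0.0, 1.0 / np.sqrt(k), k).astype(dtype))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        if c != self.config.channels:
            raise ValueError(f"expected {self.config.channels} channels, got {c}")
        v = nn.global_avg_pool(x)                       # (N, C)
        w = nn.conv1d_channels(v, self.kernel).sigmoid()
        return x * w.reshape(n, c, 1, 1)


class DUC(nn.Module):
    """Dense Upsampling Convolution: 3x3 conv to C*r^2 then sub-pixel reshape."""

    def __init__(self, config: DUCConfig, rng=None, dtype=np.float32):
        super().__init__()
        self.config = config
        self.conv = nn.Conv2d(config.channels, config.intermediate_channels,
                              3, padding=1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.config.ratio == 1:
            return y
        return nn.pixel_shuffle(y, self.config.ratio)


class Bottleneck(nn.Module):
    """1x1 reduce -> 3x3 (carries the stride) -> 1x1 expand(x4), BN + ReLU."""

    expansion = 4

    def __init__(self, in_ch: int, width: int, stride: int = 1,
                 frozen_bn: bool = False, rng=None, dtype=np.float32):
        super().__init__()
        out_ch = width * self.expansion
        self.conv1 = nn.Conv2d(in_ch, width, 1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(width, frozen=frozen_bn, dtype=dtype)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1,
                               bias=False, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(width, frozen=frozen_bn, dtype=dtype)
        self.conv3 = nn.Conv2d(width, out_ch, 1, bias=False, rng=rng, dtype=dtype)
        self.bn3 = nn.BatchNorm2d(out_ch, frozen=frozen_bn, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng, dtype=dtype)
            self.down_bn = nn.BatchNorm2d(out_ch, frozen=frozen_bn, dtype=dtype)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        idt = x
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        if self.down_conv is not None:
            idt = self.down_bn(self.down_conv(x))
        return (y + idt).relu()


class ResNetStages(nn.Module):
    """Residual stem + four bottleneck stages returning (C2, C3, C4, C5).

    Full-scale geometry (stem 64, widths 64/128/256/512, blocks 3/4/6/3)
    gives stage channels 256/512/1024/2048 at strides 4/8/16/32 and 16
    bottlenecks in total.
    """

    def __init__(self, stem_width: int = 64, widths=(64, 128, 256, 512),
                 blocks=(3, 4, 6, 3), frozen_bn: bool = False, rng=None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stem_conv = nn.Conv2d(3, stem_width, 7, stride=2, padding=3,
                                   bias=False, rng=rng, dtype=dtype)
        self.stem_bn = nn.BatchNorm2d(stem_width, frozen=frozen_bn, dtype=dtype)
        self.stages = []
        in_ch = stem_width
        for si, (w, n) in enumerate(zip(widths, blocks)):
            stage = []
            for bi in range(n):
                stride = 2 if (bi == 0 and si > 0) else 1
                stage.append(Bottleneck(in_ch, w, stride, frozen_bn, rng, dtype))
                in_ch = w * Bottleneck.expansion
            self.stages.append(nn.Sequential(*stage))
        self.stage_channels = tuple(w * Bottleneck.expansion for w in widths)

    def forward(self, x: Tensor):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) RGB input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"input sides must be divisible by 32, got {x.shape[2:]}"
                             " (pad before the stem)")
        y = self.stem_bn(self.stem_conv(x)).relu()
        y = nn.max_pool2d(y, 3, 2, padding=1)
        outs = []
        for stage in self.stages:
            y = stage(y)
            outs.append(y)
        return tuple(outs)          # C2, C3, C4, C5


class FPNED(nn.Module):
    """Top-down pyramid fusion with per-stage ECA and DUC upsampling.

    Each stage map passes its ECA gate, is reduced to `out_channels` by a 1x1
    lateral convolution, fused top-down (DUC r=2 upsample + elementwise add),
    and smoothed by a 3x3 anti-aliasing convolution.  P6 = stride-2 max-pool
    of the post-3x3 P5.  ``use_duc=False`` swaps DUC for nearest-neighbour
    upsampling (the baseline fusion) without changing any shape.
    """

    def __init__(self, stage_channels, out_channels: int = 256,
                 use_eca: bool = True, use_duc: bool = True,
                 gamma: float = 2.0, b: float = 1.0, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.out_channels = out_channels
        self.use_duc = use_duc
        self.ecas = [ECAModule(ECAConfig(c, gamma, b), rng, dtype) if use_eca else None
                     for c in stage_channels]
        self.laterals = [nn.Conv2d(c, out_channels, 1, rng=rng, dtype=dtype)
                         for c in stage_channels]
        self.ducs = [DUC(DUCConfig(out_channels, 2), rng, dtype) if use_duc else None
                     for _ in range(len(stage_channels) - 1)]
        self.smooths = [nn.Conv2d(out_channels, out_channels, 3, padding=1,
                                  rng=rng, dtype=dtype)
                        for _ in stage_channels]

    def forward(self, stage_maps) -> FeaturePyramid:
        if len(stage_maps) != len(self.laterals):
            raise ValueError("stage count mismatch")
        gated = []
        for eca, c in zip(self.ecas, stage_maps):
            gated.append(eca(c) if eca is not None else c)
        lat = [l(g) for l, g in zip(self.laterals, gated)]
        fused = [None] * len(lat)
        fused[-1] = lat[-1]
        for i in range(len(lat) - 2, -1, -1):
            up = (self.ducs[i](fused[i + 1]) if self.use_duc
                  else nn.upsample_nearest(fused[i + 1], 2))
            if up.shape != lat[i].shape:
                raise ValueError(
                    f"shape mismatch fusing level P{i + 2}: {up.shape} vs {lat[i].shape}")
            fused[i] = lat[i] + up
        outs = [s(f) for s, f in zip(self.smooths, fused)]
        p6 = nn.max_pool2d(outs[-1], 1, 2)
        levels = {f"P{i + 2}": t for i, t in enumerate(outs)}
        levels["P6"] = p6
        return FeaturePyramid(levels=levels, channels=self.out_channels)


class BackboneED(nn.Module):
    """ResNet stages + ECA/DUC pyramid: image (N, 3, H, W) -> P2..P6."""

    def __init__(self, stem_width=64, widths=(64, 128, 256, 512),
                 blocks=(3, 4, 6, 3), fpn_channels=256, use_eca=True,
                 use_duc=True, gamma=2.0, b=1.0, frozen_bn=False,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.resnet = ResNetStages(stem_width, widths, blocks, frozen_bn, rng, dtype)
        self.fpn = FPNED(self.resnet.stage_channels, fpn_channels, use_eca,
                         use_duc, gamma, b, rng, dtype)
        self.fpn_channels = fpn_channels

    @classmethod
    def full_scale(cls, **kw) -> "BackboneED":
        """Full ResNet50-FPN-ED geometry (256-channel pyramid)."""
        return cls(**kw)

    @classmethod
    def test_scale(cls, rng=None, dtype=np.float32, **kw) -> "BackboneED":
        """CPU-sized preset: one bottleneck per stage, widths / 4, 64-channel
        pyramid; the full ED topology (ECA + DUC wiring) is preserved."""
        kw.setdefault("stem_width", 16)
        kw.setdefault("widths", (16, 32, 64, 128))
        kw.setdefault("blocks", (1, 1, 1, 1))
        kw.setdefault("fpn_channels", 64)
        kw.setdefault("frozen_bn", True)
        return cls(rng=rng, dtype=dtype, **kw)

    def forward(self, x: Tensor) -> FeaturePyramid:
        return self.fpn(self.resnet(x))
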