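"""The aggregation-and-attention segmentation network.

A U-Net-shaped encoder-decoder with four bespoke blocks:

* **EDS** (enhanced down-sampling) encoder stages: a residual double
  convolution ``maxpool(convBNReLU(convBNReLU(x)) + convBNReLU_1x1(x))``
  plus a fused side feature combining the low-level and high-level
  activations of the double conv, which feeds both the multi-scale skip
  connection and a deep-supervision head.
* **MSC** (multi-scale connection): replaces the plain skip connection with
  four parallel branches — a 1x1 conv and three 3x3 dilated convs at rates
  6/12/18 (padding = rate, so spatial size is preserved) — concatenated and
  fused back to the stage width.
* **DAF** (dual-attention fusion) bottleneck: two 3x3 convs followed by a
  positional-attention head (softmax affinity over all pixel pairs) and a
  convolution-free channel-attention head (softmax affinity over channel
  pairs), each with a learnable residual scale, fused by variant DAF1/2/3.
* **US** (up-sampling) decoder stages: bilinear 2x upsampling + 1x1 conv of
  the deeper feature, concatenation with the MSC feature at the same level,
  then the same residual double-conv structure as EDS (without pooling),
  plus a deep-supervision head.

Every supervision head projects to the three nested region channels
(WT, CT, ET) and is bilinearly upsampled to the input resolution, so one
loss routine applies to all heads.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import Tensor
from .nn import tensor as F

DAF_VARIANTS = ("DAF1", "DAF2", "DAF3")


@dataclasses.dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``base_channels`` sets the first encoder stage width; widths double per
    stage (the U-Net convention).  ``msc_positions`` selects which of the
    four skip connections use the multi-scale block (position 1 = largest
    feature map); a position not listed falls back to a plain skip.
    ``eds_supervision`` / ``us_supervision`` toggle the encoder/decoder
    deep-supervision heads.
    """

    base_channels: int = 32
    n_stages: int = 4
    in_channels: int = 4
    n_region_channels: int = 3
    dilation_rates: Tuple[int, int, int] = (6, 12, 18)
    daf_variant: str = "DAF1"
    attention_scale_init: float = 0.0
    msc_positions: Tuple[int, ...] = (1, 2, 3, 4)
    eds_supervision: bool = True
    us_supervision: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.daf_variant not in DAF_VARIANTS:
            raise ValueError(f"unknown DAF variant {self.daf_variant!r}; "
                             f"choose from {DAF_VARIANTS}")
        if self.n_stages != 4:
            raise ValueError("the architecture is defined for 4 stages")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        bad = set(self.msc_positions) - set(range(1, self.n_stages + 1))
        if bad:
            raise ValueError(f"invalid MSC positions {sorted(bad)}")

    @property
    def stage_widths(self) -> Tuple[int, ...]:
        return tuple(self.base_channels * 2 ** s for s in range(self.n_stages))

    @property
    def bottleneck_channels(self) -> int:
        return self.stage_widths[-1] * 2


@dataclasses.dataclass
class SupervisionBundle:
    """All prediction heads needed by the deep-supervision total loss.

    Every entry is a logits tensor of shape (B, 3, H, W) at the input
    resolution (region channel order WT, CT, ET).
    """

    eds_logits: List[Tensor]
    us_logits: List[Tensor]
    daf_logits: Optional[Tensor]
    final_logits: Tensor

    @property
    def n_heads(self) -> int:
        return (len(self.eds_logits) + len(self.us_logits)
                + (self.daf_logits is not None) + 1)


class _Head(nn.Module):
    """1x1 projection to region logits, upsampled to the output resolution."""

    def __init__(self, in_channels: int, n_regions: int, rng):
        super().__init__()
        self.proj = nn.Conv2d(in_channels, n_regions, 1, rng=rng)

    def forward(self, x: Tensor, out_hw: Tuple[int, int]) -> Tensor:
        return F.resize_bilinear(self.proj(x), *out_hw)


class EDSBlock(nn.Module):
    """Enhanced down-sampling encoder stage."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        if out_channels % 2:
            raise ValueError("EDS stage width must be even")
        self.conv1 = nn.ConvBNReLU(in_channels, out_channels, 3, padding=1, rng=rng)
        self.conv2 = nn.ConvBNReLU(out_channels, out_channels, 3, padding=1, rng=rng)
        self.res = nn.ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        # fusion of the low-level (after conv1) and high-level (after conv2)
        # activations back to the stage width
        self.fuse_low = nn.ConvBNReLU(out_channels, out_channels // 2, 1, rng=rng)
        self.fuse_high = nn.ConvBNReLU(out_channels, out_channels // 2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"EDS input spatial dims {x.shape[2:]} not divisible by 2")
        g1 = self.conv1(x)
        g2 = self.conv2(g1)
        r = self.res(x)
        h = F.maxpool2d(g2 + r, 2)
        a = F.concat([self.fuse_low(g1), self.fuse_high(g2)], axis=1)
        return h, a


class MSCBlock(nn.Module):
    """Multi-scale connection: 1x1 + dilated 3x3 branches, fused."""

    def __init__(self, channels: int, rates: Sequence[int], rng):
        super().__init__()
        self.rates = tuple(rates)
        self.branch_1x1 = nn.Conv2d(channels, channels, 1, rng=rng)
        self.branches = [nn.Conv2d(channels, channels, 3, padding=r, dilation=r,
                                   rng=rng) for r in self.rates]
        self.fuse = nn.ConvBNReLU(channels * (1 + len(self.rates)), channels, 1,
                                  rng=rng)

    def forward(self, a: Tensor) -> Tensor:
        if a.shape[2] <= 0 or a.shape[3] <= 0:
            raise ValueError("MSC input must have positive spatial dims")
        parts = [self.branch_1x1(a)] + [b(a) for b in self.branches]
        return self.fuse(F.concat(parts, axis=1))


class PositionalAttention(nn.Module):
    """Spatial self-attention: softmax affinity over all pixel pairs.

    Query/key projections reduce channels to C/8; the output is
    ``alpha * (value-weighted sum) + x`` with a learnable scalar ``alpha``
    initialized so the block starts as an exact identity.
    """

    def __init__(self, channels: int, scale_init: float = 0.0, rng=None):
        super().__init__()
        reduced = max(1, channels // 8)
        self.query = nn.Conv2d(channels, reduced, 1, rng=rng)
        self.key = nn.Conv2d(channels, reduced, 1, rng=rng)
        self.value = nn.Conv2d(channels, channels, 1, rng=rng)
        self.alpha = nn.Parameter(np.array(scale_init))

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        b, c, h, w = x.shape
        n = h * w
        if n == 0:
            raise ValueError("positional attention needs a non-empty spatial grid")
        q = self.query(x).reshape(b, -1, n)          # "A" projection
        k = self.key(x).reshape(b, -1, n)            # "B" projection
        v = self.value(x).reshape(b, c, n)           # "C" projection
        energy = F.matmul(k.swapaxes(1, 2), q)       # [b, j, i] = A_i . B_j
        s = F.softmax(energy, axis=-1)               # rows (over i) sum to 1
        out = F.matmul(v, s.swapaxes(1, 2))          # out_j = sum_i s_ji C_i
        ea = self.alpha * out.reshape(b, c, h, w) + x
        return ea, s


class ChannelAttention(nn.Module):
    """Channel self-attention computed directly from the feature map.

    No convolutions are involved, preserving the raw channel relationships;
    consequently the block is equivariant under channel permutation.
    """

    def __init__(self, scale_init: float = 0.0):
        super().__init__()
        self.beta = nn.Parameter(np.array(scale_init))

    def forward(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        b, c, h, w = x.shape
        if c == 0:
            raise ValueError("channel attention needs at least one channel")
        xf = x.reshape(b, c, h * w)
        energy = F.matmul(xf, xf.swapaxes(1, 2))     # [b, j, i] = x_j . x_i
        m = F.softmax(energy, axis=-1)               # rows (over i) sum to 1
        out = F.matmul(m, xf)                        # out_j = sum_i m_ji x_i
        ca = self.beta * out.reshape(b, c, h, w) + x
        return ca, m


class DAFBlock(nn.Module):
    """Dual-attention fusion bottleneck with the three fusion variants.

    All variants share the double-conv trunk ``y`` and both attention heads:

    * DAF1 (default): ``fused = conv(EA(y) + CA(y))``
    * DAF2: a parallel 1x1 feature branch ``y'`` of the input;
      ``fused = conv(concat(EA(y) + y', CA(y) + y'))``
    * DAF3: both paths; ``fused = conv(concat(EA + CA, EA + y', CA + y'))``
    """

    def __init__(self, in_channels: int, channels: int, n_regions: int,
                 variant: str = "DAF1", scale_init: float = 0.0, rng=None):
        super().__init__()
        if variant not in DAF_VARIANTS:
            raise ValueError(f"unknown DAF variant {variant!r}")
        self.variant = variant
        self.conv1 = nn.ConvBNReLU(in_channels, channels, 3, padding=1, rng=rng)
        self.conv2 = nn.ConvBNReLU(channels, channels, 3, padding=1, rng=rng)
        self.pa = PositionalAttention(channels, scale_init, rng=rng)
        self.ca = ChannelAttention(scale_init)
        if variant != "DAF1":
            self.side = nn.ConvBNReLU(in_channels, channels, 1, rng=rng)
        n_cat = {"DAF1": 1, "DAF2": 2, "DAF3": 3}[variant]
        self.fuse = nn.Conv2d(channels * n_cat, channels, 1, rng=rng)
        self.head = _Head(channels, n_regions, rng)

    def forward(self, x: Tensor, out_hw: Tuple[int, int]) -> Tuple[Tensor, Tensor]:
        y = self.conv2(self.conv1(x))
        ea, _ = self.pa(y)
        ca, _ = self.ca(y)
        if self.variant == "DAF1":
            fused = self.fuse(ea + ca)
        elif self.variant == "DAF2":
            side = self.side(x)
            fused = self.fuse(F.concat([ea + side, ca + side], axis=1))
        else:
            side = self.side(x)
            fused = self.fuse(F.concat([ea + ca, ea + side, ca + side], axis=1))
        return fused, self.head(fused, out_hw)


class USBlock(nn.Module):
    """Up-sampling decoder stage: upsample, concatenate skip, residual convs."""

    def __init__(self, prev_channels: int, skip_channels: int, out_channels: int,
                 rng):
        super().__init__()
        self.up_proj = nn.Conv2d(prev_channels, prev_channels, 1, rng=rng)
        cin = prev_channels + skip_channels
        self.conv1 = nn.ConvBNReLU(cin, out_channels, 3, padding=1, rng=rng)
        self.conv2 = nn.ConvBNReLU(out_channels, out_channels, 3, padding=1, rng=rng)
        self.res = nn.ConvBNReLU(cin, out_channels, 1, rng=rng)

    def forward(self, prev: Tensor, skip: Tensor) -> Tensor:
        th, tw = skip.shape[2], skip.shape[3]
        if (prev.shape[2] * 2, prev.shape[3] * 2) != (th, tw):
            raise ValueError(
                f"US stage expects skip at twice the previous resolution: "
                f"prev {prev.shape[2:]} vs skip {skip.shape[2:]}")
        up = self.up_proj(F.resize_bilinear(prev, th, tw))
        x = F.concat([up, skip], axis=1)
        return self.conv2(self.conv1(x)) + self.res(x)


class AANet(nn.Module):
    """The full aggregation-and-attention network.

    ``forward`` maps a (B, 4, H, W) input (H, W divisible by 16) to a
    :class:`SupervisionBundle` with up to 4 encoder heads, up to 4 decoder
    heads, the bottleneck head and the final prediction head, all at
    (B, 3, H, W).
    """

    def __init__(self, config: NetConfig = None,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.config = config = config or NetConfig()
        rng = rng or np.random.default_rng(config.seed)
        widths = config.stage_widths
        nr = config.n_region_channels

        self.eds = []
        cin = config.in_channels
        for width in widths:
            self.eds.append(EDSBlock(cin, width, rng))
            cin = width
        self.eds_heads = [_Head(w, nr, rng) for w in widths]
        self.msc = [MSCBlock(w, config.dilation_rates, rng)
                    if (s + 1) in config.msc_positions else None
                    for s, w in enumerate(widths)]
        self.daf = DAFBlock(widths[-1], config.bottleneck_channels, nr,
                            config.daf_variant, config.attention_scale_init, rng)
        self.us = []
        prev = config.bottleneck_channels
        for width in reversed(widths):
            self.us.append(USBlock(prev, width, width, rng))
            prev = width
        self.us_heads = [_Head(w, nr, rng) for w in reversed(widths)]
        self.final_head = nn.Conv2d(widths[0], nr, 1, rng=rng)

    def forward(self, x) -> SupervisionBundle:
        x = nn.astensor(x)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected (B, {cfg.in_channels}, H, W) input, got {x.shape}")
        h, w = x.shape[2], x.shape[3]
        div = 2 ** cfg.n_stages
        if h % div or w % div:
            raise ValueError(f"spatial dims {h}x{w} must be divisible by {div}")
        out_hw = (h, w)

        feats = []
        cur = x
        for block in self.eds:
            cur, a = block(cur)
            feats.append(a)
        eds_logits = ([head(a, out_hw) for head, a in zip(self.eds_heads, feats)]
                      if cfg.eds_supervision else [])
        skips = [m(a) if m is not None else a for m, a in zip(self.msc, feats)]

        fused, daf_logits = self.daf(cur, out_hw)

        us_logits = []
        cur = fused
        for block, head, skip in zip(self.us, self.us_heads, reversed(skips)):
            cur = block(cur, skip)
            if cfg.us_supervision:
                us_logits.append(head(cur, out_hw))
        final_logits = self.final_head(cur)
        return SupervisionBundle(eds_logits=eds_logits, us_logits=us_logits,
                                 daf_logits=daf_logits, final_logits=final_logits)

    def predict_regions(self, x, threshold: float = 0.5,
                        enforce_nesting: bool = False) -> np.ndarray:
        """Binarized (B, 3, H, W) region masks from the final head (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                probs = F.sigmoid(self.forward(x).final_logits).data
        finally:
            self.train(was_training)
        masks = probs >= threshold
        if enforce_nesting:  # ET <= CT <= WT by intersection
            masks[:, 1] &= masks[:, 0]
            masks[:, 2] &= masks[:, 1]
        return masks
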