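"""Deep attentive feature fusion head over a four-level feature pyramid.

Each pyramid level is projected to a common width (the single-layer features,
SLF) and brought to the level-1 grid (half the input resolution, the fusion
scale).  The four SLFs are concatenated and fused into the multi-layer
features (MLF).  Per level, an attention module looks at (SLF_i, MLF) and
emits sigmoid weights A_i in (0,1); the gated MLF' = A_i (*) MLF is merged
back with SLF_i by a small refinement stack.  The four refined (attentive)
features are concatenated, pooled through a dilated-convolution pyramid
(ASPP) and reduced to the main segmentation logit.  Deep supervision taps a
1x1x1 head off every SLF and every refined feature, giving 4 + 4 auxiliary
probability maps next to the main output, all upsampled to input resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import nn
from ._autodiff import tensor as T
from ._autodiff.tensor import Tensor, as_tensor
from .encoder import FeaturePyramid

_F32 = np.float32


@dataclass
class HeadConfig:
    """Widths and rates of the fusion head.

    ``lateral_channels`` is the SLF width; the MLF carries four times that.
    ``attn_hidden`` is the width of the two hidden attention convolutions
    (a bottleneck; the final convolution maps to the MLF width for gating).
    """

    lateral_channels: int = 64
    aspp_rates: tuple[int, ...] = (1, 2, 3, 4)
    groupnorm_groups: int = 8
    attn_hidden: int | None = None

    def __post_init__(self):
        if self.lateral_channels <= 0:
            raise ValueError("lateral_channels must be positive")
        if any(r < 1 for r in self.aspp_rates) or not self.aspp_rates:
            raise ValueError("aspp_rates must be a non-empty tuple of ints >= 1")
        if self.attn_hidden is None:
            self.attn_hidden = self.lateral_channels

    @property
    def mlf_channels(self) -> int:
        return 4 * self.lateral_channels


@dataclass
class PredictionSet:
    """Main + deep-supervision probability maps, all at input resolution."""

    main: Tensor
    aux_slf: list
    aux_attn: list

    def __post_init__(self):
        if len(self.aux_slf) != 4 or len(self.aux_attn) != 4:
            raise ValueError("expected 4 SLF and 4 attentive auxiliary maps")

    def arrays(self) -> dict:
        return {"main": self.main.data,
                "aux_slf": [t.data for t in self.aux_slf],
                "aux_attn": [t.data for t in self.aux_attn]}

    def binarize(self, threshold: float = 0.5) -> np.ndarray:
        return (self.main.data > threshold).astype(np.uint8)


def _gn_groups(groups: int, channels: int) -> int:
    while channels % groups:
        groups -= 1
    return max(groups, 1)


class ConvBlock(nn.Module):
    """Conv3d + group norm + PReLU, the standard unit of the head."""

    def __init__(self, c_in, c_out, kernel, groups, rng, dilation=1):
        super().__init__()
        self.conv = nn.Conv3d(c_in, c_out, kernel, rng, dilation=dilation)
        self.norm = nn.GroupNorm(_gn_groups(groups, c_out), c_out)
        self.act = nn.PReLU(c_out)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


def upsample_to(x: Tensor, target_extents) -> Tensor:
    """Repeatedly double spatial axes (trilinear) then crop to the target."""
    th, tw, td = target_extents
    while x.shape[0] < th or x.shape[1] < tw or x.shape[2] < td:
        for axis in range(3):
            if x.shape[axis] < target_extents[axis]:
                x = T.upsample2(x, axis)
    return x[:th, :tw, :td, :]


class AttentionModule(nn.Module):
    """Three-convolution attention over (SLF_i, MLF) ending in a sigmoid.

    With all parameters zero the logits are zero, so every attention weight
    is exactly 0.5; outputs are always strictly inside (0, 1).
    """

    def __init__(self, cfg: HeadConfig, rng):
        super().__init__()
        cin = cfg.lateral_channels + cfg.mlf_channels
        self.block1 = ConvBlock(cin, cfg.attn_hidden, 3, cfg.groupnorm_groups, rng)
        self.block2 = ConvBlock(cfg.attn_hidden, cfg.attn_hidden, 3, cfg.groupnorm_groups, rng)
        self.final = nn.Conv3d(cfg.attn_hidden, cfg.mlf_channels, 3, rng)

    def forward(self, slf: Tensor, mlf: Tensor) -> Tensor:
        if slf.shape[:3] != mlf.shape[:3]:
            raise ValueError(f"SLF extents {slf.shape[:3]} != MLF extents {mlf.shape[:3]}")
        x = T.concat([slf, mlf], axis=-1)
        return T.sigmoid(self.final(self.block2(self.block1(x))))


class RefineModule(nn.Module):
    """Merge the gated MLF with the level's SLF: two 3x3x3 convs + one 1x1x1."""

    def __init__(self, cfg: HeadConfig, rng):
        super().__init__()
        cin = cfg.mlf_channels + cfg.lateral_channels
        L = cfg.lateral_channels
        self.block1 = ConvBlock(cin, L, 3, cfg.groupnorm_groups, rng)
        self.block2 = ConvBlock(L, L, 3, cfg.groupnorm_groups, rng)
        self.final = nn.Conv3d(L, L, 1, rng)

    def forward(self, slf: Tensor, mlf: Tensor, attention: Tensor) -> Tensor:
        gated = attention * mlf                     # MLF' = A_i (*) MLF
        x = T.concat([gated, slf], axis=-1)
        return self.final(self.block2(self.block1(x)))


class ASPP(nn.Module):
    """Parallel dilated 3x3x3 branches plus a 1x1x1 branch, concatenated.

    A dilation whose receptive offset would exceed the grid is clamped (with
    a warning) so every branch still sees real voxels.
    """

    def __init__(self, c_in, branch_channels, rates, groups, rng):
        super().__init__()
        self.rates = tuple(rates)
        self.point = ConvBlock(c_in, branch_channels, 1, groups, rng)
        self.branches = [ConvBlock(c_in, branch_channels, 3, groups, rng, dilation=r)
                         for r in self.rates]
        c_cat = branch_channels * (len(self.rates) + 1)
        self.project = ConvBlock(c_cat, c_in, 1, groups, rng)

    def forward(self, x: Tensor) -> Tensor:
        min_extent = min(x.shape[:3])
        outs = [self.point(x)]
        for rate, branch in zip(self.rates, self.branches):
            eff = min(rate, max(1, min_extent - 1))
            if eff != rate:
                warnings.warn(f"ASPP rate {rate} clamped to {eff} for extents {x.shape[:3]}",
                              stacklevel=2)
            outs.append(branch.act(branch.norm(
                T.conv3d(x, branch.conv.weight, branch.conv.bias, dilation=eff))))
        return self.project(T.concat(outs, axis=-1))


class DAFHead(nn.Module):
    """The full fusion head: laterals -> MLF -> attention -> refine -> ASPP -> heads."""

    def __init__(self, stage_dims, cfg: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        L = cfg.lateral_channels
        g = cfg.groupnorm_groups
        self.laterals = [ConvBlock(dim, L, 1, g, rng) for dim in stage_dims]
        self.fuse = ConvBlock(4 * L, cfg.mlf_channels, 3, g, rng)
        self.attentions = [AttentionModule(cfg, rng) for _ in range(4)]
        self.refines = [RefineModule(cfg, rng) for _ in range(4)]
        self.aspp = ASPP(4 * L, L, cfg.aspp_rates, g, rng)
        self.post = ConvBlock(4 * L, L, 3, g, rng)
        self.main_head = nn.Conv3d(L, 1, 1, rng)
        self.slf_heads = [nn.Conv3d(L, 1, 1, rng) for _ in range(4)]
        self.attn_heads = [nn.Conv3d(L, 1, 1, rng) for _ in range(4)]

    # -- stages exposed individually (testable contracts) ------------------
    def project_laterals(self, pyramid: FeaturePyramid) -> list:
        if len(pyramid.levels) != 4:
            raise ValueError(f"expected a 4-level pyramid, got {len(pyramid.levels)}")
        target = pyramid.levels[0].features.shape[:3]
        slfs = []
        for lateral, level in zip(self.laterals, pyramid.levels):
            slfs.append(upsample_to(lateral(level.features), target))
        return slfs

    def fuse_mlf(self, slfs: list) -> Tensor:
        extents = {s.shape[:3] for s in slfs}
        if len(extents) != 1:
            raise ValueError(f"SLF extents differ: {extents}")
        return self.fuse(T.concat(slfs, axis=-1))

    def attention_weights(self, level: int, slf: Tensor, mlf: Tensor) -> Tensor:
        return self.attentions[level](slf, mlf)

    def refine(self, level: int, slf: Tensor, mlf: Tensor, attention: Tensor) -> Tensor:
        return self.refines[level](slf, mlf, attention)

    def forward(self, pyramid: FeaturePyramid, out_extents) -> PredictionSet:
        slfs = self.project_laterals(pyramid)
        mlf = self.fuse_mlf(slfs)
        refined = []
        for i in range(4):
            a = self.attention_weights(i, slfs[i], mlf)
            refined.append(self.refine(i, slfs[i], mlf, a))
        y = self.post(self.aspp(T.concat(refined, axis=-1)))

        def head_to_prob(head, feats):
            logit = upsample_to(head(feats), out_extents)
            return T.sigmoid(logit[..., 0])

        main = head_to_prob(self.main_head, y)
        aux_slf = [head_to_prob(h, s) for h, s in zip(self.slf_heads, slfs)]
        aux_attn = [head_to_prob(h, r) for h, r in zip(self.attn_heads, refined)]
        return PredictionSet(main=main, aux_slf=aux_slf, aux_attn=aux_attn)
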