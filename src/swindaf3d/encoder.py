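"""Four-stage hierarchical shifted-window transformer encoder for 3D volumes.

The encoder embeds a volume into non-overlapping 2x2x2 patches, runs stacks of
window-attention blocks (alternating regular and shifted window partitions so
neighbouring windows exchange information), and halves the token grid between
stages with patch merging.  Its output is a four-level feature pyramid at
scales 1/2, 1/4, 1/8, 1/16 of the input with channel widths C, 2C, 4C, 8C.

Token grids are channels-last ``(h, w, d, C)`` tensors; windows are cubes of
``window**3`` tokens.  Border handling is zero padding plus attention masking,
so partitioning followed by its inverse is exact for any extents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import nn
from ._autodiff import tensor as T
from ._autodiff.tensor import Tensor, as_tensor

_F32 = np.float32
_NEG_INF = _F32(-np.inf)


@dataclass
class EncoderConfig:
    """Hyperparameters of the hierarchical window-attention encoder.

    ``embed_dim`` (the "feature size") and ``window`` default to the 48 /
    7x7x7 configuration used at clinical scale; depths (2,2,2,2) and heads
    (3,6,12,24) are the standard small-variant stage layout.
    """

    embed_dim: int = 48
    window: int = 7
    depths: tuple[int, ...] = (2, 2, 2, 2)
    heads: tuple[int, ...] = (3, 6, 12, 24)
    patch: int = 2
    use_relative_bias: bool = True
    mlp_ratio: int = 4

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("depths and heads must each have 4 stages")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for i, h in enumerate(self.heads):
            if (self.embed_dim * 2 ** i) % h:
                raise ValueError(
                    f"stage {i}: channels {self.embed_dim * 2 ** i} not divisible by heads {h}")

    @property
    def stage_dims(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * 2 ** i for i in range(4))


@dataclass
class TokenGrid:
    """A channels-last feature grid with its downsampling factor."""

    features: Tensor
    scale: int = 1


@dataclass
class FeaturePyramid:
    levels: list[TokenGrid]

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError(f"expected 4 pyramid levels, got {len(self.levels)}")


@dataclass
class WindowBatch:
    """Tokens tiled into non-overlapping windows plus masking metadata."""

    windows: Tensor                      # (nW, window**3, C)
    attn_mask: np.ndarray                # (nW, 1, window**3, window**3), additive 0/-inf
    valid: np.ndarray                    # (nW, window**3) bool, False on padding
    original_extents: tuple[int, int, int]
    padded_extents: tuple[int, int, int]
    window: int
    shift: int
    grid_shape: tuple                    # (nh, nw, nd) window counts per axis


def _axis_labels(length: int, window: int, shift: int) -> np.ndarray:
    """Origin-region labels along one padded axis, in the rolled frame.

    After a cyclic shift by ``-shift`` the only discontiguity lands inside the
    last window, splitting it into content from the far end (label 1) and
    wrapped content from the near end (label 2); everything else is label 0.
    """
    lab = np.zeros(length, dtype=np.int64)
    if shift > 0:
        lab[length - window:length - shift] = 1
        lab[length - shift:] = 2
    return lab


def partition_windows(grid, window: int, shift: int = 0) -> WindowBatch:
    """Tile a token grid into ``window**3`` blocks, cyclically shifted by ``-shift``.

    ``shift`` must be 0 (regular partition) or ``window // 2`` (shifted
    partition).  The attention mask forbids pairs whose tokens were not
    neighbours before the cyclic shift and masks padded positions as keys.
    """
    grid = as_tensor(grid)
    if window < 1:
        raise ValueError("window must be >= 1")
    if shift not in (0, window // 2):
        raise ValueError(f"shift must be 0 or window//2={window // 2}, got {shift}")
    h, w, d, c = grid.shape
    pads = tuple((-e) % window for e in (h, w, d))
    hp, wp, dp = h + pads[0], w + pads[1], d + pads[2]

    x = grid
    if any(pads):
        x = T.pad(x, ((0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
    if shift > 0:
        x = T.roll(x, (-shift, -shift, -shift), (0, 1, 2))

    nh, nw, nd = hp // window, wp // window, dp // window
    x = T.reshape(x, (nh, window, nw, window, nd, window, c))
    x = T.transpose(x, (0, 2, 4, 1, 3, 5, 6))
    windows = T.reshape(x, (nh * nw * nd, window ** 3, c))

    # validity mirrors the exact transforms applied to the features
    valid_grid = np.zeros((hp, wp, dp), dtype=bool)
    valid_grid[:h, :w, :d] = True
    if shift > 0:
        valid_grid = np.roll(valid_grid, (-shift, -shift, -shift), (0, 1, 2))
    region = (_axis_labels(hp, window, shift)[:, None, None] * 9
              + _axis_labels(wp, window, shift)[None, :, None] * 3
              + _axis_labels(dp, window, shift)[None, None, :])

    def tile(a):
        return (a.reshape(nh, window, nw, window, nd, window)
                .transpose(0, 2, 4, 1, 3, 5)
                .reshape(nh * nw * nd, window ** 3))

    valid = tile(valid_grid)
    reg = tile(region)
    allowed = (reg[:, :, None] == reg[:, None, :]) & valid[:, None, :]
    nwin, n = valid.shape
    eye = np.eye(n, dtype=bool)
    allowed |= eye[None, :, :]  # self-attention always defined, even on padding
    attn_mask = np.where(allowed, _F32(0.0), _NEG_INF)[:, None, :, :]

    return WindowBatch(windows=windows, attn_mask=attn_mask, valid=valid,
                       original_extents=(h, w, d), padded_extents=(hp, wp, dp),
                       window=window, shift=shift, grid_shape=(nh, nw, nd))


def reverse_windows(windows, batch: WindowBatch) -> Tensor:
    """Exact inverse of :func:`partition_windows` (un-tile, un-shift, un-pad)."""
    windows = as_tensor(windows)
    nh, nw, nd = batch.grid_shape
    wsize = batch.window
    c = windows.shape[-1]
    x = T.reshape(windows, (nh, nw, nd, wsize, wsize, wsize, c))
    x = T.transpose(x, (0, 3, 1, 4, 2, 5, 6))
    hp, wp, dp = batch.padded_extents
    x = T.reshape(x, (hp, wp, dp, c))
    if batch.shift > 0:
        x = T.roll(x, (batch.shift, batch.shift, batch.shift), (0, 1, 2))
    h, w, d = batch.original_extents
    if (hp, wp, dp) != (h, w, d):
        x = x[:h, :w, :d, :]
    return x


def _relative_index(window: int) -> np.ndarray:
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window), np.arange(window),
                                  indexing="ij"), axis=-1).reshape(-1, 3)
    rel = coords[:, None, :] - coords[None, :, :] + (window - 1)
    m = 2 * window - 1
    return (rel[..., 0] * m * m + rel[..., 1] * m + rel[..., 2]).astype(np.int64)


class WindowAttention(nn.Module):
    """Multi-head self-attention inside windows, with relative position bias."""

    def __init__(self, dim: int, heads: int, window: int, rng: np.random.Generator,
                 use_relative_bias: bool = True):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.window = window
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.use_relative_bias = use_relative_bias
        self.keep_attn = False       # stash attention probabilities for inspection
        self.last_attn: np.ndarray | None = None
        if use_relative_bias:
            m = 2 * window - 1
            self.bias_table = nn.Parameter(nn.trunc_normal(rng, (m ** 3, heads)))
            self.bias_index = _relative_index(window)

    def forward(self, batch: WindowBatch) -> Tensor:
        x = batch.windows
        nwin, n, c = x.shape
        qkv = self.qkv(x)
        qkv = T.reshape(qkv, (nwin, n, 3, self.heads, self.head_dim))
        qkv = T.transpose(qkv, (2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = T.matmul(q, T.transpose(k, (0, 1, 3, 2))) * self.scale
        if self.use_relative_bias:
            bias = T.gather0(self.bias_table, self.bias_index)      # (n, n, heads)
            scores = scores + T.transpose(bias, (2, 0, 1))
        scores = scores + Tensor(batch.attn_mask)
        attn = T.softmax(scores, axis=-1)
        if self.keep_attn:
            self.last_attn = attn.data
        out = T.matmul(attn, v)                                      # (nW, heads, n, dh)
        out = T.reshape(T.transpose(out, (0, 2, 1, 3)), (nwin, n, c))
        out = self.proj(out)
        # padded query rows pass through as exact zeros
        return out * Tensor(batch.valid[:, :, None].astype(_F32))


class Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(T.gelu(self.fc1(x)))


class SwinBlock(nn.Module):
    """Pre-norm window attention + MLP, each with a residual connection.

    ``shift=0`` gives the regular partition (W-MSA); ``shift=window//2`` the
    shifted partition (SW-MSA).  Blocks within a stage alternate the two.
    """

    def __init__(self, dim: int, heads: int, window: int, shift: int,
                 rng: np.random.Generator, mlp_ratio: int = 4, use_relative_bias: bool = True):
        super().__init__()
        self.window = window
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, window, rng, use_relative_bias)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio * dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        batch = partition_windows(self.norm1(x), self.window, self.shift)
        attended = self.attn(batch)
        x = x + reverse_windows(attended, batch)
        return x + self.mlp(self.norm2(x))


class PatchEmbed(nn.Module):
    """Flatten non-overlapping 2x2x2 voxel patches and project them to C channels."""

    def __init__(self, embed_dim: int, rng: np.random.Generator, patch: int = 2):
        super().__init__()
        if patch != 2:
            raise ValueError("only patch size 2 is supported")
        self.patch = patch
        self.proj = nn.Linear(patch ** 3, embed_dim, rng)

    def forward(self, volume) -> Tensor:
        x = as_tensor(volume)
        if x.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {x.shape}")
        h, w, d = x.shape
        if min(h, w, d) < 2:
            raise ValueError(f"volume extents must be >= 2, got {x.shape}")
        pads = tuple((-e) % 2 for e in (h, w, d))
        if any(pads):
            x = T.pad(x, ((0, pads[0]), (0, pads[1]), (0, pads[2])))
        h2, w2, d2 = (h + pads[0]) // 2, (w + pads[1]) // 2, (d + pads[2]) // 2
        x = T.reshape(x, (h2, 2, w2, 2, d2, 2))
        x = T.transpose(x, (0, 2, 4, 1, 3, 5))
        x = T.reshape(x, (h2, w2, d2, 8))
        return self.proj(x)


class PatchMerging(nn.Module):
    """Concatenate 2x2x2 token neighbourhoods, normalise, project to 2x channels."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = nn.LayerNorm(8 * dim)
        self.reduce = nn.Linear(8 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        h, w, d, c = x.shape
        pads = tuple((-e) % 2 for e in (h, w, d))
        if any(pads):
            x = T.pad(x, ((0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
        h2, w2, d2 = (h + pads[0]) // 2, (w + pads[1]) // 2, (d + pads[2]) // 2
        x = T.reshape(x, (h2, 2, w2, 2, d2, 2, c))
        x = T.transpose(x, (0, 2, 4, 1, 3, 5, 6))
        x = T.reshape(x, (h2, w2, d2, 8 * c))
        return self.reduce(self.norm(x))


class SwinEncoder(nn.Module):
    """The full four-stage encoder producing a feature pyramid."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.embed = PatchEmbed(config.embed_dim, rng, config.patch)
        self.embed_norm = nn.LayerNorm(config.embed_dim)
        stages = []
        for i, (depth, heads) in enumerate(zip(config.depths, config.heads)):
            dim = config.embed_dim * 2 ** i
            blocks = []
            for b in range(depth):
                shift = 0 if b % 2 == 0 else config.window // 2
                blocks.append(SwinBlock(dim, heads, config.window, shift, rng,
                                        config.mlp_ratio, config.use_relative_bias))
            stages.append(nn.Sequential(*blocks))
        self.stages = stages
        self.merges = [PatchMerging(config.embed_dim * 2 ** i, rng) for i in range(3)]

    def forward(self, volume) -> FeaturePyramid:
        vol = as_tensor(volume)
        if min(vol.shape) < 16:
            raise ValueError(
                f"volume extents {vol.shape} too small for four halvings (need >= 16)")
        x = self.embed_norm(self.embed(vol))
        levels = []
        for i in range(4):
            x = self.stages[i](x)
            levels.append(TokenGrid(features=x, scale=2 ** (i + 1)))
            if i < 3:
                x = self.merges[i](x)
        return FeaturePyramid(levels=levels)


def encode(volume, config: EncoderConfig, seed: int = 0) -> FeaturePyramid:
    """Convenience wrapper: build a freshly initialised encoder and run it."""
    enc = SwinEncoder(config, np.random.default_rng(seed))
    return enc(volume)
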