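"""Structural tests of the shifted-window transformer encoder."""

import numpy as np
import pytest

from swindaf3d._autodiff import Tensor
from swindaf3d._autodiff import tensor as T
from swindaf3d.encoder import (EncoderConfig, PatchEmbed, PatchMerging, SwinBlock,
                               SwinEncoder, WindowAttention, partition_windows,
                               reverse_windows)

RNG = np.random.default_rng(11)


def rand_grid(*shape):
    return Tensor(RNG.normal(size=shape).astype(np.float32))


# ---------------------------------------------------------------------------
# patch embedding / merging shape laws
# ---------------------------------------------------------------------------

def test_embed_shape_even_extents():
    emb = PatchEmbed(12, np.random.default_rng(0))
    out = emb(RNG.random((64, 64, 32), dtype=np.float32))
    assert out.shape == (32, 32, 16, 12)


def test_embed_shape_odd_extent_pads_up():
    emb = PatchEmbed(8, np.random.default_rng(0))
    out = emb(RNG.random((9, 8, 8), dtype=np.float32))
    assert out.shape == (5, 4, 4, 8)


def test_embed_zero_volume_zero_projection():
    emb = PatchEmbed(6, np.random.default_rng(0))
    emb.proj.weight.data[:] = 0
    out = emb(np.zeros((8, 8, 4), dtype=np.float32))
    assert np.all(out.data == 0)


def test_embed_rejects_degenerate_axis():
    emb = PatchEmbed(6, np.random.default_rng(0))
    with pytest.raises(ValueError):
        emb(np.zeros((1, 8, 8), dtype=np.float32))


@pytest.mark.parametrize("in_shape,out_shape", [
    ((32, 32, 16, 12), (16, 16, 8, 24)),
    ((5, 4, 4, 10), (3, 2, 2, 20)),
])
def test_merge_shapes(in_shape, out_shape):
    merge = PatchMerging(in_shape[-1], np.random.default_rng(0))
    assert merge(rand_grid(*in_shape)).shape == out_shape


# ---------------------------------------------------------------------------
# window partitioning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("extents,window,shift", [
    ((14, 14, 14), 7, 0),
    ((8, 8, 8), 7, 0),
    ((8, 8, 8), 7, 3),
    ((9, 6, 5), 4, 0),
    ((9, 6, 5), 4, 2),
])
def test_partition_is_a_partition(extents, window, shift):
    """Every real token lands in exactly one window position."""
    n = int(np.prod(extents))
    grid = Tensor(np.arange(n, dtype=np.float32).reshape(extents + (1,)))
    batch = partition_windows(grid, window, shift)
    real = batch.windows.data[batch.valid, 0]
    assert sorted(real.tolist()) == list(range(n))


def test_partition_counts_divisible_grid():
    batch = partition_windows(rand_grid(14, 14, 14, 3), 7, 0)
    assert batch.windows.shape[0] == 8
    assert batch.valid.all()


def test_partition_pads_to_window_multiple():
    batch = partition_windows(rand_grid(8, 8, 8, 3), 7, 0)
    assert batch.padded_extents == (14, 14, 14)
    assert batch.windows.shape[0] == 8
    assert batch.valid.sum() == 8 ** 3


@pytest.mark.parametrize("shift", [0, 3])
def test_partition_reverse_roundtrip(shift):
    grid = rand_grid(10, 9, 8, 5)
    batch = partition_windows(grid, 7, shift)
    back = reverse_windows(batch.windows, batch)
    np.testing.assert_array_equal(back.data, grid.data)


def test_partition_rejects_bad_shift():
    with pytest.raises(ValueError):
        partition_windows(rand_grid(8, 8, 8, 2), 7, 2)


def test_shifted_mask_blocks_wrapped_pairs():
    """In a shifted partition, wrapped tokens must not attend to non-neighbours."""
    batch = partition_windows(rand_grid(14, 14, 14, 1), 7, 3)
    # the final window along each axis mixes origin regions -> some -inf entries
    assert np.isinf(batch.attn_mask).any()
    # regular partition of a divisible grid has no masking at all
    batch0 = partition_windows(rand_grid(14, 14, 14, 1), 7, 0)
    assert not np.isinf(batch0.attn_mask).any()


# ---------------------------------------------------------------------------
# window attention
# ---------------------------------------------------------------------------

def dense_attention_oracle(tokens, wqkv, bqkv, wproj, bproj, heads):
    """Brute-force full attention over a flat token list (float64)."""
    n, c = tokens.shape
    dh = c // heads
    qkv = tokens @ wqkv + bqkv
    q, k, v = qkv[:, :c], qkv[:, c:2 * c], qkv[:, 2 * c:]
    out = np.zeros((n, c))
    for h in range(heads):
        qh = q[:, h * dh:(h + 1) * dh]
        kh = k[:, h * dh:(h + 1) * dh]
        vh = v[:, h * dh:(h + 1) * dh]
        s = qh @ kh.T / np.sqrt(dh)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        out[:, h * dh:(h + 1) * dh] = a @ vh
    return out @ wproj + bproj


def test_windowed_equals_dense_when_window_covers_grid():
    """With one window spanning the grid, masked window attention must match
    a dense brute-force reference on the real tokens (1e-5)."""
    extents, c, heads = (5, 4, 3), 6, 2
    grid = rand_grid(*extents, c)
    attn = WindowAttention(c, heads, 7, np.random.default_rng(3), use_relative_bias=False)
    batch = partition_windows(grid, 7, 0)
    out = reverse_windows(attn(batch), batch)

    tokens = grid.data.reshape(-1, c).astype(np.float64)
    ref = dense_attention_oracle(tokens, attn.qkv.weight.data.astype(np.float64),
                                 attn.qkv.bias.data.astype(np.float64),
                                 attn.proj.weight.data.astype(np.float64),
                                 attn.proj.bias.data.astype(np.float64), heads)
    np.testing.assert_allclose(out.data.reshape(-1, c), ref, atol=1e-5)


def test_attention_rows_sum_to_one_and_masked_zero():
    attn = WindowAttention(4, 2, 3, np.random.default_rng(5))
    attn.keep_attn = True
    batch = partition_windows(rand_grid(4, 4, 4, 4), 3, 1)
    attn(batch)
    probs = attn.last_attn  # (nW, heads, n, n)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
    masked = np.isinf(batch.attn_mask[:, 0])
    assert np.all(probs[:, 0][masked] == 0.0)
    assert np.all(probs[:, 1][masked] == 0.0)


def test_single_token_window_attention_is_projected_v():
    c = 4
    attn = WindowAttention(c, 2, 1, np.random.default_rng(2), use_relative_bias=False)
    grid = rand_grid(2, 2, 1, c)
    batch = partition_windows(grid, 1, 0)
    out = reverse_windows(attn(batch), batch)
    qkv = grid.data.reshape(-1, c) @ attn.qkv.weight.data + attn.qkv.bias.data
    v = qkv[:, 2 * c:]
    expected = v @ attn.proj.weight.data + attn.proj.bias.data
    np.testing.assert_allclose(out.data.reshape(-1, c), expected, atol=1e-5)


def test_identical_keys_give_uniform_attention():
    """All keys equal -> softmax uniform -> output is the projected mean V."""
    c, heads = 6, 3
    attn = WindowAttention(c, heads, 3, np.random.default_rng(4), use_relative_bias=False)
    token = RNG.normal(size=c).astype(np.float32)
    grid = Tensor(np.broadcast_to(token, (3, 3, 3, c)).copy())
    batch = partition_windows(grid, 3, 0)
    out = reverse_windows(attn(batch), batch)
    qkv = token @ attn.qkv.weight.data + attn.qkv.bias.data
    v = qkv[2 * c:]
    expected = v @ attn.proj.weight.data + attn.proj.bias.data
    np.testing.assert_allclose(out.data.reshape(-1, c),
                               np.broadcast_to(expected, (27, c)), atol=1e-5)


# ---------------------------------------------------------------------------
# blocks and full encoder
# ---------------------------------------------------------------------------

def test_zero_projection_block_is_identity():
    block = SwinBlock(8, 2, 3, 0, np.random.default_rng(6))
    block.attn.proj.weight.data[:] = 0
    block.attn.proj.bias.data[:] = 0
    block.mlp.fc2.weight.data[:] = 0
    block.mlp.fc2.bias.data[:] = 0
    grid = rand_grid(5, 4, 4, 8)
    np.testing.assert_array_equal(block(grid).data, grid.data)


def test_block_preserves_shape():
    block = SwinBlock(8, 2, 3, 1, np.random.default_rng(6))
    grid = rand_grid(5, 4, 4, 8)
    assert block(grid).shape == grid.shape


def test_stage_blocks_alternate_shift():
    cfg = EncoderConfig(embed_dim=8, window=5, depths=(2, 2, 2, 2), heads=(2, 2, 4, 8))
    enc = SwinEncoder(cfg, np.random.default_rng(0))
    shifts = [b.shift for b in enc.stages[0].mods]
    assert shifts == [0, 5 // 2]


@pytest.mark.parametrize("shape,c,expected", [
    ((64, 64, 32), 12, [(32, 32, 16, 12), (16, 16, 8, 24), (8, 8, 4, 48), (4, 4, 2, 96)]),
    ((32, 32, 16), 48, [(16, 16, 8, 48), (8, 8, 4, 96), (4, 4, 2, 192), (2, 2, 1, 384)]),
])
def test_pyramid_shape_law(shape, c, expected):
    """Extents halve (ceil) and channels double at every level."""
    heads = (2, 4, 4, 8) if c == 12 else (3, 6, 12, 24)
    cfg = EncoderConfig(embed_dim=c, window=3, depths=(1, 1, 1, 1), heads=heads)
    enc = SwinEncoder(cfg, np.random.default_rng(1))
    pyr = enc(RNG.random(shape, dtype=np.float32))
    assert [lvl.features.shape for lvl in pyr.levels] == expected
    assert [lvl.scale for lvl in pyr.levels] == [2, 4, 8, 16]


def test_encoder_deterministic():
    cfg = EncoderConfig(embed_dim=8, window=3, depths=(1, 1, 1, 1), heads=(2, 2, 4, 8))
    vol = RNG.random((16, 16, 16), dtype=np.float32)
    p1 = SwinEncoder(cfg, np.random.default_rng(9))(vol)
    p2 = SwinEncoder(cfg, np.random.default_rng(9))(vol)
    for a, b in zip(p1.levels, p2.levels):
        np.testing.assert_array_equal(a.features.data, b.features.data)


def test_encoder_rejects_small_volume():
    cfg = EncoderConfig(embed_dim=8, window=3, depths=(1, 1, 1, 1), heads=(2, 2, 4, 8))
    enc = SwinEncoder(cfg, np.random.default_rng(0))
    with pytest.raises(ValueError):
        enc(np.zeros((8, 8, 8), dtype=np.float32))


def test_config_validates_head_divisibility():
    with pytest.raises(ValueError):
        EncoderConfig(embed_dim=10, heads=(3, 6, 12, 24))
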