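"""Metric correctness against brute-force oracles, plus statistics harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swindaf3d.metrics import dice_score, extract_surface, iou, surface_dice
from swindaf3d.stats import (FoldTable, load_benchmark_folds, summarize_folds,
                             wilcoxon_compare)

RNG = np.random.default_rng(51)


# ---------------------------------------------------------------------------
# brute-force oracles (nested loops / all-pairs distances)
# ---------------------------------------------------------------------------

def brute_counts(a, b):
    inter = union = na = nb = 0
    for idx in np.ndindex(a.shape):
        av, bv = bool(a[idx]), bool(b[idx])
        inter += av and bv
        union += av or bv
        na += av
        nb += bv
    return inter, union, na, nb


def brute_surface(mask):
    out = np.zeros_like(mask, dtype=bool)
    H, W, D = mask.shape
    for i, j, k in np.ndindex(mask.shape):
        if not mask[i, j, k]:
            continue
        on_surface = False
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < H and 0 <= nj < W and 0 <= nk < D) or not mask[ni, nj, nk]:
                on_surface = True
                break
        out[i, j, k] = on_surface
    return out


def brute_surface_dice(a, b, d):
    sa = np.argwhere(brute_surface(a))
    sb = np.argwhere(brute_surface(b))
    if len(sa) + len(sb) == 0:
        return 1.0
    if len(sa) == 0 or len(sb) == 0:
        return 0.0
    close_ab = sum(1 for p in sa if min(np.sqrt(((p - q) ** 2).sum()) for q in sb) <= d)
    close_ba = sum(1 for q in sb if min(np.sqrt(((q - p) ** 2).sum()) for p in sa) <= d)
    return (close_ab + close_ba) / (len(sa) + len(sb))


def rand_mask(shape=(8, 8, 8), p=0.25, rng=RNG):
    return (rng.random(shape) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# examples
# ---------------------------------------------------------------------------

def test_dice_identity_and_disjoint():
    a = rand_mask(p=0.4)
    assert dice_score(a, a) == 1.0
    b = np.zeros_like(a)
    b[0, 0, 0] = 1
    c = np.zeros_like(a)
    c[-1, -1, -1] = 1
    assert dice_score(b, c) == 0.0


def test_dice_counted_overlap():
    a = np.zeros((4, 4, 4), np.uint8)
    b = np.zeros((4, 4, 4), np.uint8)
    a[0, 0, :4] = 1
    a[0, 1, :4] = 1          # |A| = 8
    b[0, 1, :4] = 1
    b[0, 2, :4] = 1          # |B| = 8, overlap 4
    assert dice_score(a, b) == pytest.approx(0.5)
    assert iou(a, b) == pytest.approx(4 / 12)


def test_both_empty_convention():
    z = np.zeros((3, 3, 3), np.uint8)
    assert dice_score(z, z) == 1.0
    assert iou(z, z) == 1.0
    assert surface_dice(z, z, 1.0) == 1.0


def test_extents_mismatch_raises():
    with pytest.raises(ValueError):
        dice_score(np.zeros((3, 3, 3), np.uint8), np.zeros((3, 3, 2), np.uint8))


def test_cube_surface_is_26_voxels():
    m = np.zeros((5, 5, 5), np.uint8)
    m[1:4, 1:4, 1:4] = 1
    assert int(extract_surface(m).sum()) == 26


def test_single_voxel_is_its_own_surface():
    m = np.zeros((3, 3, 3), np.uint8)
    m[1, 1, 1] = 1
    s = extract_surface(m)
    assert s.sum() == 1 and s[1, 1, 1]


def test_grid_boundary_counts_as_surface():
    m = np.ones((3, 3, 3), np.uint8)
    assert int(extract_surface(m).sum()) == 26  # all but the centre voxel


def test_surface_dice_distant_voxels():
    a = np.zeros((7, 7, 7), np.uint8)
    b = np.zeros((7, 7, 7), np.uint8)
    a[1, 1, 1] = 1
    b[4, 1, 1] = 1          # distance 3 > 1
    assert surface_dice(a, b, 1.0) == 0.0


def test_surface_dice_shifted_cube_within_tolerance():
    a = np.zeros((8, 8, 8), np.uint8)
    b = np.zeros((8, 8, 8), np.uint8)
    a[2:5, 2:5, 2:5] = 1
    b[3:6, 2:5, 2:5] = 1    # shift by one voxel
    assert surface_dice(a, b, 1.0) == pytest.approx(brute_surface_dice(a, b, 1.0))
    assert surface_dice(a, b, 1.0) == 1.0


def test_surface_dice_tolerance_limit_is_one():
    a = rand_mask(p=0.3)
    b = rand_mask(p=0.3)
    if a.any() and b.any():
        assert surface_dice(a, b, 1e9) == 1.0


# ---------------------------------------------------------------------------
# oracle equivalence and properties
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_metrics_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    a = rand_mask((6, 6, 6), rng.uniform(0.1, 0.5), rng)
    b = rand_mask((6, 6, 6), rng.uniform(0.1, 0.5), rng)
    inter, union, na, nb = brute_counts(a, b)
    expected_dsc = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
    expected_iou = 1.0 if union == 0 else inter / union
    assert dice_score(a, b) == pytest.approx(expected_dsc, abs=1e-12)
    assert iou(a, b) == pytest.approx(expected_iou, abs=1e-12)
    np.testing.assert_array_equal(extract_surface(a), brute_surface(a.astype(bool)))
    assert surface_dice(a, b, 1.0) == pytest.approx(brute_surface_dice(a, b, 1.0), abs=1e-12)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_metric_symmetry_and_dsc_iou_relation(seed):
    rng = np.random.default_rng(seed)
    a, b = rand_mask(rng=rng), rand_mask(rng=rng)
    assert dice_score(a, b) == dice_score(b, a)
    assert iou(a, b) == iou(b, a)
    assert surface_dice(a, b, 1.0) == surface_dice(b, a, 1.0)
    j = iou(a, b)
    assert dice_score(a, b) == pytest.approx(2 * j / (1 + j), abs=1e-12)


def test_growing_intersection_is_monotone():
    base = np.zeros((6, 6, 6), np.uint8)
    base[1:5, 1:5, 1:5] = 1
    pred = np.zeros_like(base)
    pred[1:5, 1:5, 0:1] = 1   # |pred| fixed as it slides into the truth
    scores = []
    for shift in range(1, 5):
        p = np.roll(pred, shift, axis=2)
        scores.append((dice_score(p, base), iou(p, base)))
    assert all(s2 >= s1 for (s1, _), (s2, _) in zip(scores, scores[1:]))


# ---------------------------------------------------------------------------
# fold summaries and Wilcoxon
# ---------------------------------------------------------------------------

def test_summarize_folds_closed_form():
    s = summarize_folds([0.0, 1.0])
    assert s.mean == 0.5 and s.std == 0.5


def test_summarize_constant_folds_zero_std():
    s = summarize_folds([0.8] * 6)
    assert s.std == pytest.approx(0.0, abs=1e-12)


def test_summarize_benchmark_best_model_column():
    s = summarize_folds([0.854, 0.815, 0.841, 0.832, 0.849, 0.835])
    assert round(s.mean, 3) == 0.838
    assert round(s.std, 3) == 0.013


def test_summarize_rejects_single_value():
    with pytest.raises(ValueError):
        summarize_folds([1.0])


def test_wilcoxon_equal_samples_p_one():
    r = wilcoxon_compare([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
    assert r.p_raw == 1.0 and r.n == 0


def test_wilcoxon_six_same_sign_exact():
    """All six differences positive: exact two-sided p = 2/64."""
    a = [0.85, 0.81, 0.84, 0.83, 0.85, 0.83]
    b = [x - 0.01 * i for i, x in enumerate(a, 1)]
    r = wilcoxon_compare(a, b, sided="two")
    assert r.p_raw == pytest.approx(2 / 64, abs=1e-12)
    r1 = wilcoxon_compare(a, b, sided="greater")
    assert r1.p_raw == pytest.approx(1 / 64, abs=1e-12)


def test_wilcoxon_matches_scipy_exact_no_ties():
    from scipy.stats import wilcoxon as sw
    rng = np.random.default_rng(3)
    a = rng.normal(size=8)
    b = a + rng.normal(0.3, 1.0, size=8)
    ours = wilcoxon_compare(a, b, sided="two")
    ref = sw(a, b, alternative="two-sided", method="exact")
    assert ours.p_raw == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_bonferroni_adjustment():
    a = [1, 2, 3, 4, 5, 6.5]
    b = [0, 1, 2, 3, 4, 5]
    r = wilcoxon_compare(a, b, m=5)
    assert r.p_adjusted == pytest.approx(min(1.0, 5 * r.p_raw))
    assert wilcoxon_compare(a, b, m=1000).p_adjusted == 1.0


def test_wilcoxon_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        wilcoxon_compare([1, 2, 3], [1, 2])


# ---------------------------------------------------------------------------
# fold table
# ---------------------------------------------------------------------------

def test_benchmark_table_loads_and_summarizes():
    table = load_benchmark_folds()
    assert set(table.models()) == {"unet3d", "daf3d", "swin_unetr", "unetrpp",
                                   "transunet", "swindaf3d"}
    assert len(table.values("swindaf3d", "dsc")) == 6
    summary = table.summary_table()
    assert len(summary) == 18
    best = table.summarize("swindaf3d", "dsc")
    assert round(best.mean, 3) == 0.838


def test_fold_table_comparison_runs():
    table = load_benchmark_folds()
    r = table.compare("swindaf3d", "unet3d", "dsc", m=5)
    assert r.n == 6
    assert 0 < r.p_raw <= 1
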