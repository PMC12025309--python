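"""Volumetric and surface segmentation metrics.

DSC = 2|A∩B| / (|A| + |B|), IoU = |A∩B| / |A∪B|, and the surface Dice
counts surface voxels of each mask lying within a Euclidean tolerance
distance ``d`` (in voxel units) of the other mask's surface:

    SDSC = (|S_p near S_g| + |S_g near S_p|) / (|S_p| + |S_g|).

Surfaces are a mask minus its 6-connected binary erosion with zero padding,
so voxels on the grid boundary count as surface.  Distances come from exact
Euclidean distance transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegMetrics:
    dsc: float
    iou: float
    sdsc: float


def _as_bool(mask) -> np.ndarray:
    arr = mask.data if hasattr(mask, "data") else mask
    arr = np.asarray(arr)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1, True, False))):
        raise ValueError(f"mask must be binary, found values {uniq[:10]}")
    return arr.astype(bool)


def _check_pair(a, b):
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask extents differ: {a.shape} vs {b.shape}")
    return a, b


def dice_score(a, b) -> float:
    """Volumetric Dice overlap; 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def iou(a, b) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def extract_surface(mask) -> np.ndarray:
    """Boolean surface: mask minus its 6-connected erosion (zero-padded)."""
    m = _as_bool(mask)
    if not m.any():
        return np.zeros_like(m)
    eroded = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return m & ~eroded


def surface_dice(a, b, d: float = 1.0) -> float:
    """Surface Dice at tolerance ``d`` (Euclidean, voxel units)."""
    if d < 0:
        raise ValueError("tolerance d must be >= 0")
    a, b = _check_pair(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    na, nb = int(sa.sum()), int(sb.sum())
    if na + nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    dist_to_b = ndimage.distance_transform_edt(~sb)
    dist_to_a = ndimage.distance_transform_edt(~sa)
    near_ab = int((dist_to_b[sa] <= d).sum())
    near_ba = int((dist_to_a[sb] <= d).sum())
    return (near_ab + near_ba) / (na + nb)


def evaluate_masks(pred, truth, tolerance: float = 1.0) -> SegMetrics:
    """All three metrics for one predicted/ground-truth mask pair."""
    return SegMetrics(dsc=dice_score(pred, truth), iou=iou(pred, truth),
                      sdsc=surface_dice(pred, truth, tolerance))
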