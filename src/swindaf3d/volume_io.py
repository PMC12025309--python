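"""Volume and mask I/O plus the deterministic preprocessing chain.

Volumes are stored channels-free as ``(H, W, D)`` float32 grids with
millimetre voxel spacing; the axis convention is (axial, lateral, elevation).
Preprocessing for the segmentation networks is a central crop to the joint
region followed by a resize to a fixed grid (256 x 256 x 64 in the clinical
protocol) and per-volume min-max intensity normalisation to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3D grayscale intensity grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMask:
    """A binary 3D grid aligned with a :class:`Volume`."""

    data: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be binary, found {uniq[:10]}")
        self.data = arr.astype(np.uint8)

    @property
    def shape(self):
        return self.data.shape

    def volume_fraction(self) -> float:
        return float(self.data.mean())


@dataclass
class Case:
    """A volume/mask pair with an identifier."""

    id: str
    volume: Volume
    mask: LabelMask
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError(
                f"case {self.id}: volume shape {self.volume.shape} != mask shape {self.mask.shape}")

    @property
    def shape(self):
        return self.volume.shape


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    arr = np.squeeze(arr)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D single-channel image, got shape {arr.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(arr, dtype=np.float32), spacing


def read_case(volume_path, mask_path, case_id: str | None = None) -> Case:
    """Read a NIfTI volume/mask pair.

    Mask voxels are binarised at 0.5, so label files stored as {0, 255} or
    probabilities both map onto {0, 1}.
    """
    vol_arr, spacing = _load_nifti(volume_path)
    mask_arr, _ = _load_nifti(mask_path)
    if vol_arr.shape != mask_arr.shape:
        raise ValueError(
            f"volume shape {vol_arr.shape} does not match mask shape {mask_arr.shape}")
    if not np.all(np.isfinite(vol_arr)):
        raise ValueError(f"{volume_path}: non-finite intensities")
    cid = case_id if case_id is not None else Path(volume_path).name.split(".")[0]
    return Case(id=cid,
                volume=Volume(vol_arr, spacing),
                mask=LabelMask((mask_arr > 0.5).astype(np.uint8)))


def write_case(case: Case, volume_path, mask_path) -> None:
    """Write a case as a NIfTI pair; spacing goes into the header affine."""
    affine = np.diag(list(case.volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(case.volume.data.astype(np.float32), affine), str(volume_path))
    nib.save(nib.Nifti1Image(case.mask.data.astype(np.uint8), affine), str(mask_path))


def _crop_slices(shape, target):
    slices = []
    for s, t in zip(shape, target):
        if t > s:
            raise ValueError(f"crop target {target} exceeds input shape {shape}")
        off = (s - t) // 2  # floor offset on odd remainders: deterministic tie-break
        slices.append(slice(off, off + t))
    return tuple(slices)


def central_crop(case: Case, target_extent) -> Case:
    """Centred crop of volume and mask to ``target_extent`` per axis."""
    sl = _crop_slices(case.shape, tuple(target_extent))
    return Case(id=case.id,
                volume=Volume(case.volume.data[sl], case.volume.spacing),
                mask=LabelMask(case.mask.data[sl]),
                meta=dict(case.meta))


def resize(case: Case, target_shape) -> Case:
    """Resize to ``target_shape``: trilinear for the volume, nearest for the mask."""
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be positive, got {target_shape}")
    src = case.shape
    if target_shape == src:
        return case
    zoom = [t / s for t, s in zip(target_shape, src)]
    vol = ndimage.zoom(case.volume.data, zoom, order=1, mode="nearest", grid_mode=True)
    msk = ndimage.zoom(case.mask.data, zoom, order=0, mode="nearest", grid_mode=True)
    # guard against off-by-one extents from rounding inside ndimage.zoom
    vol = _fit_to(vol, target_shape)
    msk = _fit_to(msk, target_shape)
    new_spacing = tuple(sp * s / t for sp, s, t in zip(case.volume.spacing, src, target_shape))
    return Case(id=case.id, volume=Volume(vol, new_spacing),
                mask=LabelMask(msk), meta=dict(case.meta))


def _fit_to(arr, shape):
    slices = tuple(slice(0, min(a, t)) for a, t in zip(arr.shape, shape))
    arr = arr[slices]
    pads = tuple((0, t - a) for a, t in zip(arr.shape, shape))
    if any(p[1] for p in pads):
        arr = np.pad(arr, pads, mode="edge")
    return arr


def normalize_intensity(volume: Volume) -> Volume:
    """Min-max scale intensities to [0, 1]; constant volumes map to zeros."""
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume intensities must be finite")
    lo, hi = float(data.min()), float(data.max())
    if hi - lo == 0.0:
        return Volume(np.zeros_like(data), volume.spacing)
    return Volume((data - lo) / (hi - lo), volume.spacing)


def preprocess(case: Case, crop_extent=None, target_shape=(256, 256, 64)) -> Case:
    """The deterministic preprocessing chain: crop -> resize -> normalise."""
    if crop_extent is not None:
        case = central_crop(case, crop_extent)
    case = resize(case, target_shape)
    vol = normalize_intensity(case.volume)
    return Case(id=case.id, volume=vol, mask=case.mask, meta=dict(case.meta))
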