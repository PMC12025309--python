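"""Synthetic 3D B-mode ultrasound phantoms of finger joints.

Each phantom emulates the structures a linear-probe sweep of a finger joint
shows from the skin down: a bright skin band, speckled soft tissue with a
slowly varying (inhomogeneous) echogenicity, a curved hyperechoic bone
interface, an acoustic shadow attenuating everything beneath the bone, and —
the segmentation target — a hypoechoic synovium recess sitting on top of the
bone with a smooth but irregular boundary.  Speckle is modelled as unit-mean
multiplicative gamma noise, the standard first-order approximation for fully
developed B-mode speckle.

The generator is the package's stand-in for clinical data that cannot be
shared; it reproduces the qualitative challenges of the real task (ambiguous
boundaries, shape variability, intensity inhomogeneity, shadowing) but not
the physics of wave propagation.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import Case, LabelMask, Volume, write_case


@dataclass
class PhantomConfig:
    """Geometry and texture parameters of the phantom family.

    The default grid matches the preprocessed clinical volumes
    (256 x 256 x 64); tests and desk-scale runs pass smaller shapes.
    """

    shape: tuple[int, int, int] = (256, 256, 64)
    synovium_fraction_range: tuple[float, float] = (0.02, 0.10)
    speckle_scale: float = 0.3          # relative std of the gamma multiplier
    shadow_strength: float = 0.6        # 0: no shadow, 1: fully dark below bone
    bone_depth_range: tuple[float, float] = (0.55, 0.75)  # fraction of H
    contrast_gap: float = 0.5           # synovium/background mean-intensity ratio
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.synovium_fraction_range
        if not (0.0 < lo < hi < 0.5):
            raise ValueError(f"synovium_fraction_range must satisfy 0 < lo < hi < 0.5, got {(lo, hi)}")
        blo, bhi = self.bone_depth_range
        if not (0.0 < blo <= bhi < 1.0):
            raise ValueError(f"bone_depth_range must be ordered fractions of H, got {(blo, bhi)}")
        if not (0.0 < self.contrast_gap < 1.0):
            raise ValueError("contrast_gap must lie in (0, 1)")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be positive")
        if not (0.0 <= self.shadow_strength <= 1.0):
            raise ValueError("shadow_strength must lie in [0, 1]")
        if any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        self.shape = tuple(int(s) for s in self.shape)


@dataclass
class AugmentationConfig:
    """Random augmentation family emulating probe repositioning and gain/dynamic-range changes.

    Axis convention: 0 = axial (depth), 1 = lateral, 2 = elevation.  Flips are
    restricted to the lateral/elevation axes by default (a depth flip has no
    physical counterpart); rotation is about the elevation axis, i.e. in the
    axial-lateral imaging plane.
    """

    flip_axes: tuple[int, ...] = (1, 2)
    rotation_max_deg: float = 15.0
    brightness_delta: float = 0.1
    contrast_range: tuple[float, float] = (0.9, 1.1)
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    noise_std: float = 0.02
    apply_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.contrast_range[0] > self.contrast_range[1]:
            raise ValueError("contrast_range must be ordered")
        if self.blur_sigma_range[0] > self.blur_sigma_range[1]:
            raise ValueError("blur_sigma_range must be ordered")
        if min(self.rotation_max_deg, self.brightness_delta, self.noise_std) < 0:
            raise ValueError("magnitudes must be non-negative")
        if not (0.0 <= self.apply_prob <= 1.0):
            raise ValueError("apply_prob must lie in [0, 1]")
        if any(a not in (0, 1, 2) for a in self.flip_axes):
            raise ValueError("flip_axes must be a subset of (0, 1, 2)")


def _smooth_field(rng, shape, sigma_frac, amplitude):
    """Low-frequency random field: white noise blurred to ~sigma_frac of extent."""
    noise = rng.standard_normal(shape)
    sigmas = [max(1.0, sigma_frac * s) for s in shape]
    f = ndimage.gaussian_filter(noise, sigmas)
    peak = np.abs(f).max()
    if peak > 0:
        f *= amplitude / peak
    return f.astype(np.float32)


def case_seed(global_seed: int, index: int) -> np.random.SeedSequence:
    """Stable per-case seed derivation: datasets are reproducible under reordering."""
    return np.random.SeedSequence(entropy=int(global_seed), spawn_key=(int(index),))


def generate_phantom(config: PhantomConfig, seed=None, case_id: str = "phantom") -> Case:
    """Generate one phantom volume with its ground-truth synovium mask."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    H, W, D = config.shape

    # --- anatomy ---------------------------------------------------------
    skin_depth = max(1, int(round(0.05 * H)))
    depth_frac = rng.uniform(*config.bone_depth_range)
    ii = np.arange(H, dtype=np.float32)[:, None, None]
    jj = np.arange(W, dtype=np.float32)[None, :, None]
    kk = np.arange(D, dtype=np.float32)[None, None, :]

    # curved bone interface: shallow parabolic recess around the joint centre
    cx = W * rng.uniform(0.4, 0.6)
    curv = rng.uniform(0.05, 0.15) * H
    bone_depth = (depth_frac * H
                  + curv * ((jj[0, :, 0][:, None] - cx) / (0.5 * W)) ** 2
                  + _smooth_field(rng, (W, D), 0.25, 0.03 * H))
    bone_depth = np.clip(bone_depth, skin_depth + 3, H - 2).astype(np.float32)

    # --- echogenicity map (pre-speckle) ---------------------------------
    base = 0.45 + _smooth_field(rng, (H, W, D), 0.2, 0.12)  # inhomogeneous tissue
    vol = base.astype(np.float32)
    vol[:skin_depth] = rng.uniform(0.75, 0.9)               # bright skin band

    below = ii - bone_depth[None, :, :]
    bone_band = (below >= 0) & (below < 3)
    vol[bone_band] = rng.uniform(0.85, 0.95)                # hyperechoic interface

    # acoustic shadow: depth-wise exponential attenuation beneath the bone
    tau = 0.08 * H
    atten = np.ones_like(vol)
    deep = below >= 3
    atten[deep] = 1.0 - config.shadow_strength * (1.0 - np.exp(-(below[deep] - 3) / tau))

    # --- synovium blob ---------------------------------------------------
    allowed = (ii > skin_depth + 1) & (below < -1)
    lo, hi = config.synovium_fraction_range
    feasible = allowed.mean()
    if feasible <= lo:
        raise ValueError(
            f"synovium fraction range {config.synovium_fraction_range} infeasible: "
            f"only {feasible:.3f} of the grid lies between skin and bone")

    n_ell = rng.integers(2, 5)
    quad = np.full((H, W, D), np.inf, dtype=np.float32)
    for _ in range(n_ell):
        # centres hug the bone interface, where the synovial recess lives
        cw = rng.uniform(0.3, 0.7) * W
        cd = rng.uniform(0.3, 0.7) * D
        bd = float(np.interp(cw, np.arange(W), bone_depth[:, int(cd)]))
        ch = rng.uniform(0.55, 0.85) * bd
        rh = rng.uniform(0.10, 0.20) * H
        rw = rng.uniform(0.15, 0.35) * W
        rd = rng.uniform(0.25, 0.45) * D
        q = (((ii - ch) / rh) ** 2 + ((jj - cw) / rw) ** 2 + ((kk - cd) / rd) ** 2)
        quad = np.minimum(quad, q.astype(np.float32))
    quad += _smooth_field(rng, (H, W, D), 0.15, 0.35)  # irregular, ambiguous boundary

    target = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
    qvals = quad[allowed]
    # the mask is {quad < s} within the allowed band; fraction is monotone in s,
    # so the exact threshold is an order statistic of the allowed quad values
    k = int(round(target * H * W * D))
    k = min(max(k, 1), qvals.size - 1)
    s = float(np.partition(qvals, k)[k])
    mask = (quad < s) & allowed

    frac = mask.mean()
    if not (lo <= frac <= hi):
        raise ValueError(f"generated mask fraction {frac:.4f} outside {config.synovium_fraction_range}")

    vol = np.where(mask, base * config.contrast_gap, vol)   # hypoechoic target
    vol *= atten

    # --- speckle ---------------------------------------------------------
    k_shape = 1.0 / config.speckle_scale ** 2
    speckle = rng.gamma(k_shape, 1.0 / k_shape, size=vol.shape).astype(np.float32)
    vol = np.clip(vol * speckle, 0.0, 1.0).astype(np.float32)

    meta = {
        "seed": int(seed) if np.isscalar(seed) and not isinstance(seed, np.random.SeedSequence) else None,
        "bone_depth_map": bone_depth,
        "skin_depth": skin_depth,
        "mask_fraction": float(frac),
    }
    return Case(id=case_id, volume=Volume(vol, (1.0, 1.0, 1.0)),
                mask=LabelMask(mask.astype(np.uint8)), meta=meta)


def hypoechoic_contrast(case: Case) -> tuple[float, float]:
    """Mean intensity inside the mask vs. the non-shadow background.

    Background = tissue above the bone interface, below the skin band and
    outside the mask — the region a reader would compare the synovium against.
    Requires generator metadata (``bone_depth_map``, ``skin_depth``).
    """
    bone_depth = case.meta["bone_depth_map"]
    skin = case.meta["skin_depth"]
    H = case.shape[0]
    ii = np.arange(H, dtype=np.float32)[:, None, None]
    above_bone = ii < bone_depth[None, :, :]
    m = case.mask.data.astype(bool)
    bg = above_bone & ~m
    bg[:skin] = False
    return float(case.volume.data[m].mean()), float(case.volume.data[bg].mean())


def generate_phantom_for_index(config: PhantomConfig, index: int) -> Case:
    ss = case_seed(config.seed, index)
    return generate_phantom(config, seed=ss, case_id=f"phantom_{index:04d}")


def generate_dataset(config: PhantomConfig, n: int) -> list[Case]:
    """Generate ``n`` phantoms with per-case seeds hashed from (seed, index)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return [generate_phantom_for_index(config, i) for i in range(n)]


def augment(case: Case, aug: AugmentationConfig, rng=None) -> Case:
    """One random augmentation draw applied jointly to volume and mask.

    Geometric transforms (flips, small-angle rotation about the elevation
    axis) act identically on volume and mask — trilinear vs. nearest
    resampling; photometric transforms (brightness, contrast, blur, additive
    noise) act on the volume only.  Output intensities are clipped to [0, 1]
    and the mask stays exactly binary.
    """
    if rng is None:
        rng = np.random.default_rng(aug.seed)
    vol = case.volume.data.copy()
    msk = case.mask.data.copy()

    for ax in aug.flip_axes:
        if rng.random() < aug.apply_prob:
            vol = np.flip(vol, axis=ax)
            msk = np.flip(msk, axis=ax)

    if aug.rotation_max_deg > 0 and rng.random() < aug.apply_prob:
        angle = rng.uniform(-aug.rotation_max_deg, aug.rotation_max_deg)
        vol = ndimage.rotate(vol, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, axes=(0, 1), reshape=False, order=0, mode="nearest")

    if aug.brightness_delta > 0 and rng.random() < aug.apply_prob:
        vol = vol + rng.uniform(-aug.brightness_delta, aug.brightness_delta)

    clo, chi = aug.contrast_range
    if (clo, chi) != (1.0, 1.0) and rng.random() < aug.apply_prob:
        factor = rng.uniform(clo, chi)
        vol = (vol - vol.mean()) * factor + vol.mean()

    blo, bhi = aug.blur_sigma_range
    if bhi > 0 and rng.random() < aug.apply_prob:
        sigma = rng.uniform(blo, bhi)
        if sigma > 1e-3:
            vol = ndimage.gaussian_filter(vol, sigma)

    if aug.noise_std > 0 and rng.random() < aug.apply_prob:
        vol = vol + rng.normal(0.0, aug.noise_std, size=vol.shape)

    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)
    meta = {k: v for k, v in case.meta.items() if k not in ("bone_depth_map",)}
    return Case(id=case.id + "_aug", volume=Volume(np.ascontiguousarray(vol), case.volume.spacing),
                mask=LabelMask(np.ascontiguousarray(msk)), meta=meta)


def augment_dataset(cases: list[Case], aug: AugmentationConfig, copies: int = 1) -> list[Case]:
    """Offline augmentation: appends ``copies`` augmented copies per case."""
    out = list(cases)
    for c in range(copies):
        for i, case in enumerate(cases):
            ss = np.random.SeedSequence(entropy=int(aug.seed), spawn_key=(c, i))
            out.append(replace(augment(case, aug, rng=np.random.default_rng(ss)),
                               id=f"{case.id}_aug{c}"))
    return out


def write_dataset(cases: list[Case], out_dir) -> Path:
    """Write phantoms as NIfTI pairs plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "volume", "mask", "mask_fraction", "seed"])
        for case in cases:
            vp = out_dir / f"{case.id}_vol.nii.gz"
            mp = out_dir / f"{case.id}_mask.nii.gz"
            write_case(case, vp, mp)
            writer.writerow([case.id, vp.name, mp.name,
                             f"{case.mask.volume_fraction():.6f}", case.meta.get("seed")])
    return manifest
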