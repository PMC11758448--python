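"""Volume preprocessing: resampling, normalization, cropping, augmentation.

The pipeline mirrors a standard CT-to-CT translation recipe: volumes are
resampled to isotropic spacing, min-max normalized into [0, 256], fitted to a
fixed grid by center crop / symmetric zero-padding, and — during training
only — augmented by horizontal flips and right-angle in-plane rotations
before a synchronized random crop.  Every spatial operation is applied with
one shared geometry to SECT, VNC, IOM and the lesion mask, so the material
forward model commutes with preprocessing on noiseless data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PairedCase

__all__ = ["PreprocSpec", "resample", "normalize_minmax", "fit_to_grid",
           "random_crop", "augment", "resample_case", "fit_case_to_grid"]


@dataclass(frozen=True)
class PreprocSpec:
    """Preprocessing parameters (full-scale defaults; shrink for desk runs)."""

    target_spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    target_grid: tuple[int, ...] = (256, 256, 128)
    crop_size: tuple[int, ...] = (96, 96, 96)
    norm_range: tuple[float, float] = (0.0, 256.0)
    flip: bool = True
    rotate: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(c > g for c, g in zip(self.crop_size, self.target_grid)):
            raise ValueError("crop_size must not exceed target_grid")
        if not self.norm_range[0] < self.norm_range[1]:
            raise ValueError("norm_range must be ascending")


def resample(volume: np.ndarray, spacing: tuple[float, ...],
             target_spacing: tuple[float, ...], order: int = 1) -> np.ndarray:
    """Resample to ``target_spacing`` (trilinear; ``order=0`` for masks).

    Voxel centers are aligned (``grid_mode``), so the output spacing is
    exactly ``target_spacing`` and the physical extent ``n * spacing`` per
    axis is preserved to within one voxel; interpolation is linear in the
    interior with clamped (nearest) extension at the half-voxel borders.
    """
    if any(s <= 0 for s in spacing) or any(s <= 0 for s in target_spacing):
        raise ValueError("voxel spacings must be positive")
    zoom = tuple(s / t for s, t in zip(spacing, target_spacing))
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return volume.copy()
    return ndimage.zoom(volume, zoom, order=order, mode="nearest",
                        grid_mode=True, prefilter=False)


def normalize_minmax(volume: np.ndarray,
                     norm_range: tuple[float, float] = (0.0, 256.0)) -> np.ndarray:
    """Affine map of [volume.min(), volume.max()] onto ``norm_range``."""
    lo, hi = float(volume.min()), float(volume.max())
    if hi <= lo:
        raise ValueError("constant volume: min-max normalization is degenerate")
    a, b = norm_range
    return (volume - lo) * ((b - a) / (hi - lo)) + a


def fit_to_grid(volume: np.ndarray, target_grid: tuple[int, ...],
                pad_value: float = 0.0) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Center-crop and/or symmetrically zero-pad to ``target_grid``.

    Returns the fitted volume and, per axis, the (crop_offset, pad_before)
    bookkeeping needed to invert the geometry.
    """
    out = volume
    meta: list[tuple[int, int]] = []
    crops: list[slice] = []
    pads: list[tuple[int, int]] = []
    for size, target in zip(volume.shape, target_grid):
        if size > target:
            off = (size - target) // 2
            crops.append(slice(off, off + target))
            pads.append((0, 0))
            meta.append((off, 0))
        else:
            before = (target - size) // 2
            crops.append(slice(None))
            pads.append((before, target - size - before))
            meta.append((0, before))
    out = out[tuple(crops)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads, constant_values=pad_value)
    return out, meta


def _apply_to_case(case: PairedCase, fn, fn_mask) -> PairedCase:
    return PairedCase(
        sect=fn(case.sect), vnc=fn(case.vnc), iom=fn(case.iom),
        lesion_mask=fn_mask(case.lesion_mask), lesions=case.lesions,
        case_label=case.case_label, case_id=case.case_id, seed=case.seed,
        voxel_spacing=case.voxel_spacing,
        mixing_coefficient=case.mixing_coefficient)


def resample_case(case: PairedCase, target_spacing: tuple[float, ...]) -> PairedCase:
    out = _apply_to_case(
        case,
        lambda v: resample(v, case.voxel_spacing, target_spacing, order=1),
        lambda m: resample(m.astype(np.float64), case.voxel_spacing,
                           target_spacing, order=0).astype(np.int32))
    out.voxel_spacing = tuple(target_spacing)
    return out


def fit_case_to_grid(case: PairedCase, target_grid: tuple[int, ...]) -> PairedCase:
    return _apply_to_case(
        case,
        lambda v: fit_to_grid(v, target_grid)[0],
        lambda m: fit_to_grid(m, target_grid)[0])


def random_crop(case: PairedCase, crop_size: tuple[int, ...],
                rng: np.random.Generator) -> PairedCase:
    """One uniformly drawn offset, applied identically to all four volumes."""
    if any(c > s for c, s in zip(crop_size, case.shape)):
        raise ValueError(f"crop {crop_size} larger than volume {case.shape}")
    offsets = tuple(int(rng.integers(0, s - c + 1))
                    for s, c in zip(case.shape, crop_size))
    sl = tuple(slice(o, o + c) for o, c in zip(offsets, crop_size))
    return _apply_to_case(case, lambda v: v[sl].copy(), lambda m: m[sl].copy())


def augment(case: PairedCase, rng: np.random.Generator,
            flip: bool = True, rotate: bool = True) -> PairedCase:
    """Random horizontal flip and/or in-plane rotation by a multiple of 90°.

    The axial plane is spanned by the last two axes; the left-right axis is
    the last one.  Right-angle rotations keep voxel values exact (no
    interpolation), and the case label is invariant by construction.
    """
    do_flip = flip and bool(rng.integers(0, 2))
    k = int(rng.integers(0, 4)) if rotate else 0

    def geom(v: np.ndarray) -> np.ndarray:
        if do_flip:
            v = np.flip(v, axis=-1)
        if k:
            v = np.rot90(v, k=k, axes=(-2, -1))
        return v.copy()

    return _apply_to_case(case, geom, geom)
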