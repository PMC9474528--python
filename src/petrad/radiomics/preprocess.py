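"""Interpolation onto an isotropic grid and fixed-bin-size discretisation."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from petrad.imaging_io import ImageVolume, VoiMask

__all__ = ["resample_isotropic", "discretise", "crop_to_mask", "crop_volume_to_mask"]


def _resample_grid(volume_shape, spacing, origin, iso: float):
    """Output shape and per-axis voxel-index coordinates of the new grid.

    The output grid starts at the input origin (grids aligned by origin)
    and covers the input extent.
    """
    extent = [(n - 1) * s for n, s in zip(volume_shape, spacing)]
    out_shape = tuple(int(np.floor(e / iso)) + 1 for e in extent)
    if min(out_shape) < 1:
        raise ValueError("resampled grid is empty")
    # world offset of output voxel centres relative to origin, in input voxel units
    coords = [np.arange(n) * iso / s for n, s in zip(out_shape, spacing)]
    return out_shape, coords


def resample_isotropic(
    volume: ImageVolume,
    iso_spacing: float = 1.5,
    mask: VoiMask | None = None,
    order: int = 3,
) -> ImageVolume | tuple[ImageVolume, VoiMask]:
    """Cubic B-spline resampling onto an isotropic grid aligned at the origin.

    An optional mask is resampled by the same transform and re-binarised at
    0.5. Returns the volume, or ``(volume, mask)`` when a mask is given.
    """
    if iso_spacing <= 0:
        raise ValueError("iso_spacing must be positive")
    out_shape, axes = _resample_grid(volume.shape, volume.spacing, volume.origin, iso_spacing)
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    data = ndimage.map_coordinates(volume.data, coords, order=order, mode="nearest")
    out = ImageVolume(data.reshape(out_shape), (iso_spacing,) * 3, volume.origin)
    if mask is None:
        return out
    if not mask.same_grid(volume):
        raise ValueError("mask grid does not match volume grid")
    mdata = ndimage.map_coordinates(
        mask.data.astype(np.float64), coords, order=order, mode="nearest"
    )
    out_mask = VoiMask(mdata.reshape(out_shape) >= 0.5, (iso_spacing,) * 3, volume.origin)
    return out, out_mask


def discretise(
    volume: ImageVolume | np.ndarray,
    mask: VoiMask | np.ndarray,
    bin_width: float,
) -> tuple[np.ndarray, int, bool]:
    """Fixed-bin-size grey-level discretisation anchored at the in-mask minimum.

    bin(x) = floor((x - min) / width) + 1; voxels outside the mask get 0.

    Returns ``(labels, n_levels, single_bin_flag)``.
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=np.float64)
    m = mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool)
    if data.shape != m.shape:
        raise ValueError("volume and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    vals = data[m]
    lo = vals.min()
    labels = np.zeros(data.shape, dtype=np.int32)
    labels[m] = np.floor((data[m] - lo) / bin_width).astype(np.int32) + 1
    n_levels = int(labels.max())
    return labels, n_levels, n_levels == 1


def crop_to_mask(arrays: list[np.ndarray], mask: np.ndarray, margin: int = 1):
    """Crop arrays to the mask bounding box (with margin) for texture speed."""
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return [a[sl] for a in arrays], mask[sl]


def crop_volume_to_mask(
    volume: ImageVolume, mask: VoiMask, margin_mm: float = 6.0
) -> tuple[ImageVolume, VoiMask]:
    """Crop a volume/mask pair to the mask bounding box plus a margin (mm).

    The cropped grid keeps physical alignment (origin is shifted).
    """
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise ValueError("mask is empty")
    margin = [int(np.ceil(margin_mm / s)) for s in volume.spacing]
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    origin = tuple(o + int(l) * s for o, l, s in zip(volume.origin, lo, volume.spacing))
    return (
        ImageVolume(volume.data[sl], volume.spacing, origin),
        VoiMask(mask.data[sl], volume.spacing, origin),
    )
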