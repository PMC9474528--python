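"""Volume and mask I/O on NIfTI-1, plus delimited lesion tables.

Arrays are indexed (x, y, z); world coordinates are millimetres with a
diagonal (axis-aligned) affine. All downstream modules operate on the
in-memory :class:`ImageVolume` / :class:`VoiMask` types only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ImageVolume",
    "VoiMask",
    "FormatError",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_lesion_table",
    "write_lesion_table",
]


class FormatError(ValueError):
    """Raised for files that are not readable 3-D volumes."""


class AlignmentError(ValueError):
    """Raised when a mask grid does not match its parent volume grid."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid (SUV in g/mL for PET, HU for CT).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values, indexed (x, y, z).
    spacing : tuple of float
        Voxel size (sx, sy, sz) in mm; strictly positive.
    origin : tuple of float
        World position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3-D, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | VoiMask", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def voxel_centres_world(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.data.shape[a]) * self.spacing[a] for a in range(3)
        )


@dataclass
class VoiMask:
    """Binary 3-D mask sharing grid metadata with its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "ImageVolume | VoiMask", tol: float = 1e-6) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def validate(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("mask must contain at least one voxel")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _grid_from_nifti(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3-D NIfTI volume; grid metadata is preserved round-trip."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing, origin = _grid_from_nifti(img)
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, parent: ImageVolume | None = None) -> VoiMask:
    """Read a binary mask; if `parent` is given, grids must align."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    spacing, origin = _grid_from_nifti(img)
    mask = VoiMask(data > 0.5, spacing, origin)
    if parent is not None and not mask.same_grid(parent):
        raise AlignmentError(f"{path}: mask grid does not match parent volume grid")
    return mask


def write_mask(mask: VoiMask, path: str | Path) -> Path:
    """Write a mask as uint8 {0,1}; empty masks are rejected."""
    mask.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "lesion_id" in df.columns:
        df = df.set_index("lesion_id")
    return df


def write_lesion_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True, index_label="lesion_id")
    return path
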