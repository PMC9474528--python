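"""Background-corrected adaptive-threshold PET delineation.

Pipeline: optional axis-aligned boxing to exclude nearby avid structures,
SUV_peak search (mean over a 12-mm-diameter sphere of voxel centres),
local-background estimation in a spherical shell, thresholding at
``T = f * (SUV_peak - background) + background`` with f = 0.41, and
extraction of the 26-connected supra-threshold component containing the
peak. A 64-voxel minimum-size QC filter flags too-small VOIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from petrad.imaging_io import ImageVolume, VoiMask

__all__ = [
    "Box",
    "PeakResult",
    "BackgroundEstimate",
    "SegmentationResult",
    "NoLesionError",
    "apply_box",
    "box_mask",
    "sphere_offsets",
    "find_suv_peak",
    "estimate_background",
    "estimate_background_from_mask",
    "adaptive_isocontour",
    "size_filter",
    "segment_lesion",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class NoLesionError(RuntimeError):
    """No delineatable lesion (empty box, no peak, or peak <= background)."""


# box = ((x0, x1), (y0, y1), (z0, z1)), half-open voxel ranges
Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class PeakResult:
    suv_peak: float
    peak_centre: tuple[int, int, int]
    sphere_radius_mm: float = 6.0


@dataclass(frozen=True)
class BackgroundEstimate:
    value: float
    used_fallback: bool = False  # true when the shell was empty


@dataclass
class SegmentationResult:
    mask: VoiMask
    threshold: float
    background: float
    peak: PeakResult
    passed_size_filter: bool


def box_mask(shape: tuple[int, int, int], box: Box | None) -> np.ndarray:
    """Boolean in-box indicator; full grid when box is None."""
    m = np.zeros(shape, dtype=bool)
    if box is None:
        m[:] = True
        return m
    (x0, x1), (y0, y1), (z0, z1) = box
    if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1] and 0 <= z0 < z1 <= shape[2]):
        raise ValueError(f"box {box} empty or outside grid {shape}")
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def apply_box(volume: ImageVolume, box: Box | None) -> ImageVolume:
    """Replace out-of-box voxels with the in-box minimum (background-neutral).

    The sentinel can neither win the peak search nor cross any threshold
    above it. The delineation operations below additionally take the box
    explicitly and exclude outside voxels outright.
    """
    inbox = box_mask(volume.shape, box)
    data = volume.data.copy()
    data[~inbox] = data[inbox].min()
    return ImageVolume(data, volume.spacing, volume.origin)


def sphere_offsets(spacing, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centre-to-centre distance is <= radius."""
    reach = [int(np.floor(radius_mm / s)) for s in spacing]
    offs = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                d2 = (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2
                if d2 <= radius_mm**2 + 1e-9:
                    offs.append((dx, dy, dz))
    return np.array(offs, dtype=int)


def _masked_sphere_mean(data: np.ndarray, valid: np.ndarray, offsets: np.ndarray):
    """Per-voxel mean of `data` over valid voxels within the offset set."""
    num = np.zeros(data.shape)
    den = np.zeros(data.shape)
    vdata = np.where(valid, data, 0.0)
    vcnt = valid.astype(np.float64)
    for off in offsets:
        src = tuple(
            slice(max(0, -o), data.shape[a] - max(0, o)) for a, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), data.shape[a] - max(0, -o)) for a, o in enumerate(off)
        )
        num[dst] += vdata[src]
        den[dst] += vcnt[src]
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def find_suv_peak(volume: ImageVolume, box: Box | None = None, radius_mm: float = 6.0) -> PeakResult:
    """SUV_peak: max over in-box candidate centres of the sphere-mean SUV.

    Sphere membership is by voxel-centre inclusion (distance <= radius).
    Ties break to the lowest linear (C-order) index.
    """
    inbox = box_mask(volume.shape, box)
    if not inbox.any():
        raise NoLesionError("boxed region is empty")
    offs = sphere_offsets(volume.spacing, radius_mm)
    means = _masked_sphere_mean(volume.data, inbox, offs)
    means[~inbox] = -np.inf
    idx = int(np.argmax(means))  # first max in C order = lowest linear index
    centre = np.unravel_index(idx, volume.shape)
    return PeakResult(float(means[centre]), tuple(int(c) for c in centre), radius_mm)


def estimate_background(
    volume: ImageVolume,
    peak: PeakResult,
    box: Box | None = None,
    inner_mm: float = 15.0,
    outer_mm: float = 22.5,
) -> BackgroundEstimate:
    """Mean SUV in the in-box spherical shell (inner, outer] around the peak.

    Falls back to the 10th percentile of the boxed region (flagged) when
    the shell contains no voxel.
    """
    if outer_mm <= inner_mm:
        raise ValueError("outer radius must exceed inner radius")
    inbox = box_mask(volume.shape, box)
    ax = [
        (np.arange(n) - c) * s
        for n, c, s in zip(volume.shape, peak.peak_centre, volume.spacing)
    ]
    d2 = (
        (ax[0] ** 2)[:, None, None]
        + (ax[1] ** 2)[None, :, None]
        + (ax[2] ** 2)[None, None, :]
    )
    shell = (d2 > inner_mm**2) & (d2 <= outer_mm**2) & inbox
    if shell.any():
        return BackgroundEstimate(float(volume.data[shell].mean()), used_fallback=False)
    return BackgroundEstimate(float(np.percentile(volume.data[inbox], 10.0)), used_fallback=True)


def estimate_background_from_mask(
    volume: ImageVolume,
    mask: VoiMask,
    box: Box | None = None,
    inner_mm: float = 6.0,
    outer_mm: float = 15.0,
) -> BackgroundEstimate:
    """Mean SUV in a shell (inner, outer] mm outside the mask boundary.

    Distance is the Euclidean distance transform of the mask complement
    (physical spacing), so the shell tracks the lesion surface regardless
    of lesion size or shape. Falls back to the boxed-region 10th
    percentile when the shell is empty.
    """
    if outer_mm <= inner_mm:
        raise ValueError("outer radius must exceed inner radius")
    inbox = box_mask(volume.shape, box)
    dist = ndimage.distance_transform_edt(~mask.data, sampling=volume.spacing)
    shell = (dist > inner_mm) & (dist <= outer_mm) & inbox
    if shell.any():
        return BackgroundEstimate(float(volume.data[shell].mean()), used_fallback=False)
    return BackgroundEstimate(float(np.percentile(volume.data[inbox], 10.0)), used_fallback=True)


def adaptive_threshold(suv_peak: float, background: float, fraction: float = 0.41) -> float:
    """Contrast-corrected threshold T = f*(peak - bg) + bg."""
    if suv_peak <= background:
        raise NoLesionError(f"SUV_peak {suv_peak:.3g} <= background {background:.3g}")
    return fraction * (suv_peak - background) + background


def adaptive_isocontour(
    volume: ImageVolume,
    peak: PeakResult,
    background: float,
    box: Box | None = None,
    fraction: float = 0.41,
    min_voxels: int = 64,
) -> SegmentationResult:
    """Supra-threshold 26-connected component containing the peak.

    Seeded at the peak centre when that voxel itself crosses the
    threshold, otherwise at the hottest voxel within the peak sphere
    (which is >= SUV_peak >= T by the mean <= max inequality). Central
    photopenic regions excluded by the threshold are not re-added.
    """
    T = adaptive_threshold(peak.suv_peak, background, fraction)
    inbox = box_mask(volume.shape, box)
    supra = (volume.data >= T) & inbox
    if volume.data[peak.peak_centre] >= T and inbox[peak.peak_centre]:
        seed = peak.peak_centre
    else:
        offs = sphere_offsets(volume.spacing, peak.sphere_radius_mm)
        cand = np.array(peak.peak_centre) + offs
        ok = np.all((cand >= 0) & (cand < np.array(volume.shape)), axis=1)
        cand = cand[ok]
        cand = cand[inbox[tuple(cand.T)]]
        if cand.size == 0:
            raise NoLesionError("no voxel available to seed the isocontour")
        vals = volume.data[tuple(cand.T)]
        seed = tuple(int(v) for v in cand[int(np.argmax(vals))])
        if volume.data[seed] < T:
            raise NoLesionError("no supra-threshold voxel near the peak")
    labels, _ = ndimage.label(supra, structure=_CONN26)
    comp = labels == labels[seed]
    mask = VoiMask(comp, volume.spacing, volume.origin)
    mask.validate()
    return SegmentationResult(
        mask=mask,
        threshold=float(T),
        background=float(background),
        peak=peak,
        passed_size_filter=size_filter(mask, min_voxels),
    )


def size_filter(mask: VoiMask, min_voxels: int = 64) -> bool:
    """QC: VOIs below the minimum voxel count are flagged for exclusion."""
    return mask.voxel_count >= min_voxels


def segment_lesion(
    volume: ImageVolume,
    box: Box | None = None,
    fraction: float = 0.41,
    peak_radius_mm: float = 6.0,
    shell_mm: tuple[float, float] = (15.0, 22.5),
    boundary_shell_mm: tuple[float, float] = (6.0, 15.0),
    min_voxels: int = 64,
    max_iter: int = 8,
) -> SegmentationResult:
    """Full delineation chain: peak -> background -> isocontour -> QC.

    The local background is refined iteratively: the initial estimate uses
    the peak-centred shell (percentile fallback when that shell is inside
    the lesion, i.e. not below the peak), subsequent estimates use a shell
    tracking the provisional VOI boundary, until the VOI is stable. The
    iteration is deterministic and idempotent on fixed input.
    """
    peak = find_suv_peak(volume, box, peak_radius_mm)
    bg = estimate_background(volume, peak, box, *shell_mm)
    inbox = box_mask(volume.shape, box)
    if bg.value >= peak.suv_peak:
        bg = BackgroundEstimate(float(np.percentile(volume.data[inbox], 10.0)), used_fallback=True)
    seg = adaptive_isocontour(volume, peak, bg.value, box, fraction, min_voxels)
    for _ in range(max_iter):
        new_bg = estimate_background_from_mask(volume, seg.mask, box, *boundary_shell_mm)
        if new_bg.value >= peak.suv_peak:
            break
        new_seg = adaptive_isocontour(volume, peak, new_bg.value, box, fraction, min_voxels)
        if np.array_equal(new_seg.mask.data, seg.mask.data):
            seg = new_seg
            break
        seg = new_seg
    return seg
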