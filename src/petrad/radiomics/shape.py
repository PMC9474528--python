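"""Shape features (14) from the 0.5-level surface mesh of the mask.

The mesh is produced by marching cubes on the zero-padded binary mask with
physical spacing; volume via the divergence theorem, maximum diameters as
the largest pairwise vertex distance (full 3-D and per coordinate-plane
projection), axis lengths from PCA of the physical voxel-centre cloud.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape_features", "mesh_from_mask", "mesh_volume", "max_pairwise_distance"]


def mesh_from_mask(mask: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return verts, faces


def mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)


def max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; hull-accelerated when possible."""
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 50 and pts.shape[1] >= 2:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (flat) cloud: brute force below
    return float(pdist(pts).max())


def shape_features(mask: np.ndarray, spacing) -> "OrderedDict[str, float]":
    """14 shape features of a binary mask with the given voxel spacing (mm)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 1:
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxel_volume = float(np.prod(spacing))

    verts, faces = mesh_from_mask(mask, spacing)
    vol = mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    degenerate = vol <= 0 or area <= 0
    if degenerate:
        vol = n * voxel_volume
        area = max(area, 1e-12)

    coords = np.argwhere(mask) * spacing
    if n > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    out: OrderedDict[str, float] = OrderedDict()
    out["MeshVolume"] = vol
    out["VoxelVolume"] = n * voxel_volume
    out["SurfaceArea"] = area
    out["SurfaceVolumeRatio"] = area / vol
    out["Sphericity"] = float((36.0 * np.pi * vol**2) ** (1.0 / 3.0) / area)
    out["Maximum3DDiameter"] = max_pairwise_distance(verts)
    out["Maximum2DDiameterSlice"] = max_pairwise_distance(verts[:, :2])     # (x, y)
    out["Maximum2DDiameterColumn"] = max_pairwise_distance(verts[:, [0, 2]])  # (x, z)
    out["Maximum2DDiameterRow"] = max_pairwise_distance(verts[:, 1:])       # (y, z)
    out["MajorAxisLength"] = major
    out["MinorAxisLength"] = minor
    out["LeastAxisLength"] = least
    out["Elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    out["Flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    return out
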