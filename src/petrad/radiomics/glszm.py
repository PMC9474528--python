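"""Grey-level size-zone features; zones are 26-connected components of
equal grey level (single matrix, no direction dependence)."""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy import ndimage

from petrad.radiomics.registry import GLSZM
from petrad.radiomics.texture_util import entropy_bits

__all__ = ["glszm_matrix", "glszm_features"]

_CONN26 = np.ones((3, 3, 3), dtype=int)


def glszm_matrix(labels: np.ndarray, n_levels: int) -> np.ndarray:
    """P[g-1, s-1] = number of 26-connected zones of level g and size s."""
    zones: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        binary = labels == g
        if not binary.any():
            continue
        lab, nz = ndimage.label(binary, structure=_CONN26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((n_levels, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1.0
    return P


def glszm_features(labels: np.ndarray, n_levels: int) -> tuple["OrderedDict[str, float]", bool]:
    n_voxels = int((labels > 0).sum())
    P = glszm_matrix(labels, n_levels)
    ng, ns = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    nz = P.sum()
    pn = P / nz
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float(np.sum(pn * i))
    mu_j = float(np.sum(pn * j))

    out: OrderedDict[str, float] = OrderedDict()
    out["SmallAreaEmphasis"] = float(np.sum(P / j**2) / nz)
    out["LargeAreaEmphasis"] = float(np.sum(P * j**2) / nz)
    out["GrayLevelNonUniformity"] = float(np.sum(pg**2) / nz)
    out["GrayLevelNonUniformityNormalized"] = float(np.sum(pg**2) / nz**2)
    out["SizeZoneNonUniformity"] = float(np.sum(ps**2) / nz)
    out["SizeZoneNonUniformityNormalized"] = float(np.sum(ps**2) / nz**2)
    out["ZonePercentage"] = float(nz / n_voxels)
    out["GrayLevelVariance"] = float(np.sum(pn * (i - mu_i) ** 2))
    out["ZoneVariance"] = float(np.sum(pn * (j - mu_j) ** 2))
    out["ZoneEntropy"] = entropy_bits(pn.ravel())
    out["LowGrayLevelZoneEmphasis"] = float(np.sum(P / i**2) / nz)
    out["HighGrayLevelZoneEmphasis"] = float(np.sum(P * i**2) / nz)
    out["SmallAreaLowGrayLevelEmphasis"] = float(np.sum(P / (i**2 * j**2)) / nz)
    out["SmallAreaHighGrayLevelEmphasis"] = float(np.sum(P * i**2 / j**2) / nz)
    out["LargeAreaLowGrayLevelEmphasis"] = float(np.sum(P * j**2 / i**2) / nz)
    out["LargeAreaHighGrayLevelEmphasis"] = float(np.sum(P * i**2 * j**2) / nz)
    ordered = OrderedDict((k, out[k]) for k in GLSZM)
    return ordered, n_levels == 1
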