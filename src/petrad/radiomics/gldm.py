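"""Grey-level dependence features (14).

Dependence at Chebyshev distance 1 with similarity tolerance 0: the
dependence size of a voxel is 1 (itself) plus the number of its in-mask
26-neighbours with the same grey level.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from petrad.radiomics.registry import GLDM
from petrad.radiomics.texture_util import NEIGHBOURS_26, entropy_bits, shift

__all__ = ["gldm_matrix", "gldm_features"]


def gldm_matrix(labels: np.ndarray, n_levels: int) -> np.ndarray:
    """P[g-1, d-1] = number of voxels of level g with dependence size d."""
    valid = labels > 0
    dep = np.ones(labels.shape, dtype=np.int32)
    for d in NEIGHBOURS_26:
        nb = shift(labels, d, fill=0)
        dep += ((nb == labels) & (nb > 0) & valid).astype(np.int32)
    dep[~valid] = 0
    sizes = dep[valid]
    levels = labels[valid]
    P = np.zeros((n_levels, int(sizes.max())))
    np.add.at(P, (levels - 1, sizes - 1), 1.0)
    return P


def gldm_features(labels: np.ndarray, n_levels: int) -> tuple["OrderedDict[str, float]", bool]:
    P = gldm_matrix(labels, n_levels)
    ng, nd = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    nz = P.sum()
    pn = P / nz
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    mu_i = float(np.sum(pn * i))
    mu_j = float(np.sum(pn * j))

    out: OrderedDict[str, float] = OrderedDict()
    out["SmallDependenceEmphasis"] = float(np.sum(P / j**2) / nz)
    out["LargeDependenceEmphasis"] = float(np.sum(P * j**2) / nz)
    out["GrayLevelNonUniformity"] = float(np.sum(pg**2) / nz)
    out["DependenceNonUniformity"] = float(np.sum(pd**2) / nz)
    out["DependenceNonUniformityNormalized"] = float(np.sum(pd**2) / nz**2)
    out["GrayLevelVariance"] = float(np.sum(pn * (i - mu_i) ** 2))
    out["DependenceVariance"] = float(np.sum(pn * (j - mu_j) ** 2))
    out["DependenceEntropy"] = entropy_bits(pn.ravel())
    out["LowGrayLevelEmphasis"] = float(np.sum(P / i**2) / nz)
    out["HighGrayLevelEmphasis"] = float(np.sum(P * i**2) / nz)
    out["SmallDependenceLowGrayLevelEmphasis"] = float(np.sum(P / (i**2 * j**2)) / nz)
    out["SmallDependenceHighGrayLevelEmphasis"] = float(np.sum(P * i**2 / j**2) / nz)
    out["LargeDependenceLowGrayLevelEmphasis"] = float(np.sum(P * j**2 / i**2) / nz)
    out["LargeDependenceHighGrayLevelEmphasis"] = float(np.sum(P * i**2 * j**2) / nz)
    ordered = OrderedDict((k, out[k]) for k in GLDM)
    return ordered, n_levels == 1
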