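"""Grey-level run-length features over the 13 directions (averaged).

Run lengths are computed by a vectorised backward sweep: ``L[p] = 1 +
L[p + d]`` while the next voxel continues the run, iterated to a fixed
point. Runs are counted once at their start voxel.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from petrad.radiomics.registry import GLRLM
from petrad.radiomics.texture_util import DIRECTIONS_13, entropy_bits, shift

__all__ = ["glrlm_matrix", "glrlm_features_single", "glrlm_features"]


def glrlm_matrix(labels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length matrix P[g-1, l-1] = number of runs of level g, length l."""
    valid = labels > 0
    nxt = shift(labels, direction, fill=0)
    cont = valid & (nxt == labels) & (nxt > 0)           # run continues at p + d
    back = tuple(-o for o in direction)
    prv = shift(labels, back, fill=0)
    start = valid & ~((prv == labels) & (prv > 0))
    max_len = int(np.ceil(np.sqrt(3) * max(labels.shape))) + 1
    L = np.ones(labels.shape, dtype=np.int32)
    for _ in range(max_len):
        nxt_L = shift(L, direction, fill=0)
        new = np.where(cont, 1 + nxt_L, 1).astype(np.int32)
        if np.array_equal(new, L):
            break
        L = new
    lengths = L[start]
    levels = labels[start]
    P = np.zeros((n_levels, int(lengths.max()) if lengths.size else 1))
    if lengths.size:
        np.add.at(P, (levels - 1, lengths - 1), 1.0)
    return P


def glrlm_features_single(P: np.ndarray, n_voxels: int) -> "OrderedDict[str, float]":
    ng, nl = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    nr = P.sum()
    if nr == 0:
        raise ValueError("empty run-length matrix")
    pn = P / nr
    pg = P.sum(axis=1)   # per grey level
    pr = P.sum(axis=0)   # per run length
    mu_i = float(np.sum(pn * i))
    mu_j = float(np.sum(pn * j))

    out: OrderedDict[str, float] = OrderedDict()
    out["ShortRunEmphasis"] = float(np.sum(P / j**2) / nr)
    out["LongRunEmphasis"] = float(np.sum(P * j**2) / nr)
    out["GrayLevelNonUniformity"] = float(np.sum(pg**2) / nr)
    out["GrayLevelNonUniformityNormalized"] = float(np.sum(pg**2) / nr**2)
    out["RunLengthNonUniformity"] = float(np.sum(pr**2) / nr)
    out["RunLengthNonUniformityNormalized"] = float(np.sum(pr**2) / nr**2)
    out["RunPercentage"] = float(nr / n_voxels)
    out["GrayLevelVariance"] = float(np.sum(pn * (i - mu_i) ** 2))
    out["RunVariance"] = float(np.sum(pn * (j - mu_j) ** 2))
    out["RunEntropy"] = entropy_bits(pn.ravel())
    out["LowGrayLevelRunEmphasis"] = float(np.sum(P / i**2) / nr)
    out["HighGrayLevelRunEmphasis"] = float(np.sum(P * i**2) / nr)
    out["ShortRunLowGrayLevelEmphasis"] = float(np.sum(P / (i**2 * j**2)) / nr)
    out["ShortRunHighGrayLevelEmphasis"] = float(np.sum(P * i**2 / j**2) / nr)
    out["LongRunLowGrayLevelEmphasis"] = float(np.sum(P * j**2 / i**2) / nr)
    out["LongRunHighGrayLevelEmphasis"] = float(np.sum(P * i**2 * j**2) / nr)
    return out


def glrlm_features(labels: np.ndarray, n_levels: int) -> tuple["OrderedDict[str, float]", bool]:
    n_voxels = int((labels > 0).sum())
    per_dir = [
        glrlm_features_single(glrlm_matrix(labels, n_levels, d), n_voxels)
        for d in DIRECTIONS_13
    ]
    out = OrderedDict((k, float(np.mean([f[k] for f in per_dir]))) for k in GLRLM)
    return out, n_levels == 1
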