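"""Neighbourhood grey-tone difference features (5).

For each in-mask voxel with at least one in-mask 26-neighbour, the
absolute difference between its level and the mean level of those
neighbours is accumulated per grey level.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy import ndimage

from petrad.radiomics.registry import NGTDM

__all__ = ["ngtdm_table", "ngtdm_features"]

_KERNEL = np.ones((3, 3, 3))
_KERNEL[1, 1, 1] = 0.0


def ngtdm_table(labels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Returns (n_i counts, s_i summed absolute differences) per level."""
    valid = labels > 0
    vals = labels.astype(np.float64) * valid
    nbr_sum = ndimage.convolve(vals, _KERNEL, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(valid.astype(np.float64), _KERNEL, mode="constant", cval=0.0)
    has_nbr = valid & (nbr_cnt > 0.5)
    diff = np.zeros(labels.shape)
    diff[has_nbr] = np.abs(vals[has_nbr] - nbr_sum[has_nbr] / nbr_cnt[has_nbr])
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    lv = labels[has_nbr] - 1
    np.add.at(n_i, lv, 1.0)
    np.add.at(s_i, lv, diff[has_nbr])
    return n_i, s_i


def ngtdm_features(labels: np.ndarray, n_levels: int) -> tuple["OrderedDict[str, float]", bool]:
    n_i, s_i = ngtdm_table(labels, n_levels)
    N = n_i.sum()
    if N == 0:
        raise ValueError("no voxel with an in-mask neighbour")
    p = n_i / N
    i = np.arange(1, n_levels + 1, dtype=np.float64)
    pos = p > 0
    ngp = int(pos.sum())

    out: OrderedDict[str, float] = OrderedDict()
    denom_coarse = float(np.sum(p * s_i))
    out["Coarseness"] = float(1.0 / denom_coarse) if denom_coarse > 0 else 1e6
    if ngp > 1:
        pi = p[pos][:, None]
        pj = p[pos][None, :]
        ii = i[pos][:, None]
        jj = i[pos][None, :]
        out["Contrast"] = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1)) * np.sum(s_i) / N
        )
        ipi = i[pos] * p[pos]
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        out["Busyness"] = float(denom_coarse / busy_den) if busy_den > 0 else 0.0
        si = s_i[pos][:, None]
        sj = s_i[pos][None, :]
        out["Complexity"] = float(np.sum(np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)) / N)
        sum_s = float(np.sum(s_i))
        out["Strength"] = (
            float(np.sum((pi + pj) * (ii - jj) ** 2) / sum_s) if sum_s > 0 else 0.0
        )
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    ordered = OrderedDict((k, out[k]) for k in NGTDM)
    return ordered, ngp <= 1
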