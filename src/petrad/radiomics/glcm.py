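"""Grey-level co-occurrence features.

Symmetric matrices at distance 1 over the 13 unique 3-D directions,
normalised per direction; features are computed per direction and then
averaged (direction averaging, not matrix merging). Log terms mask zero
probabilities exactly (no epsilon), so brute-force oracles can match to
machine precision.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from petrad.radiomics.registry import GLCM, GLCM_EXCLUDED
from petrad.radiomics.texture_util import DIRECTIONS_13, entropy_bits, shift

__all__ = ["glcm_matrix", "glcm_features_single", "glcm_features"]


def glcm_matrix(labels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix for one direction.

    Returns an all-zero matrix when the direction has no valid pair.
    """
    a = labels
    b = shift(labels, direction, fill=0)
    valid = (a > 0) & (b > 0)
    P = np.zeros((n_levels, n_levels), dtype=np.float64)
    if valid.any():
        np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
        P = P + P.T
        P /= P.sum()
    return P


def glcm_features_single(p: np.ndarray) -> "OrderedDict[str, float]":
    """All co-occurrence features (including SumAverage and MCC) of one
    normalised symmetric matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    I = i[:, None] * np.ones((1, ng))
    J = np.ones((ng, 1)) * i[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    ks = np.arange(2, 2 * ng + 1, dtype=np.float64)            # i + j
    p_sum = np.bincount((I + J).astype(int).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    kd = np.arange(0, ng, dtype=np.float64)                    # |i - j|
    p_diff = np.bincount(np.abs(I - J).astype(int).ravel(), weights=p.ravel(), minlength=ng)

    diff_avg = float(np.sum(kd * p_diff))

    hxy = entropy_bits(p)
    pxpy = px[:, None] * py[None, :]
    m = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[m] * np.log2(pxpy[m])))
    mz = pxpy > 0
    hxy2 = float(-np.sum(pxpy[mz] * np.log2(pxpy[mz])))
    hx = entropy_bits(px)
    hy = entropy_bits(py)

    out: OrderedDict[str, float] = OrderedDict()
    out["Autocorrelation"] = float(np.sum(I * J * p))
    out["JointAverage"] = mu_x
    cdev = I + J - mu_x - mu_y
    out["ClusterProminence"] = float(np.sum(cdev**4 * p))
    out["ClusterShade"] = float(np.sum(cdev**3 * p))
    out["ClusterTendency"] = float(np.sum(cdev**2 * p))
    out["Contrast"] = float(np.sum((I - J) ** 2 * p))
    if sig_x > 0 and sig_y > 0:
        out["Correlation"] = float((np.sum(I * J * p) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        out["Correlation"] = 1.0
    out["DifferenceAverage"] = diff_avg
    out["DifferenceEntropy"] = entropy_bits(p_diff)
    out["DifferenceVariance"] = float(np.sum((kd - diff_avg) ** 2 * p_diff))
    out["JointEnergy"] = float(np.sum(p**2))
    out["JointEntropy"] = hxy
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    out["Imc2"] = float(np.sqrt(1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))
    absdiff = np.abs(I - J)
    out["Idm"] = float(np.sum(p / (1.0 + (I - J) ** 2)))
    out["Idmn"] = float(np.sum(p / (1.0 + ((I - J) / ng) ** 2)))
    out["Id"] = float(np.sum(p / (1.0 + absdiff)))
    out["Idn"] = float(np.sum(p / (1.0 + absdiff / ng)))
    off = absdiff > 0
    out["InverseVariance"] = float(np.sum(p[off] / (I - J)[off] ** 2))
    out["MaximumProbability"] = float(p.max())
    out["SumEntropy"] = entropy_bits(p_sum)
    out["SumSquares"] = float(np.sum((I - mu_x) ** 2 * p))
    # excluded-by-default members, kept for reconciliation
    out["SumAverage"] = float(np.sum(ks * p_sum))
    out["MCC"] = _mcc(p, px, py)
    return out


def _mcc(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    obs = px > 0
    if obs.sum() < 2:
        return 1.0
    q = p[np.ix_(obs, obs)]
    qx = px[obs]
    qy = py[obs]
    A = q / qx[:, None]
    B = q / qy[None, :]
    Q = A @ B.T
    eig = np.sort(np.linalg.eigvals(Q).real)[::-1]
    if len(eig) < 2:
        return 1.0
    return float(np.sqrt(max(eig[1], 0.0)))


def glcm_features(
    labels: np.ndarray, n_levels: int, include_excluded: bool = False
) -> tuple["OrderedDict[str, float]", bool]:
    """Direction-averaged co-occurrence features.

    Returns ``(features, degenerate_flag)``; the flag is set for a single
    grey level or when no direction produced a valid pair (features then
    take their defined limits).
    """
    names = GLCM + (GLCM_EXCLUDED if include_excluded else [])
    per_dir: list[OrderedDict[str, float]] = []
    for d in DIRECTIONS_13:
        P = glcm_matrix(labels, n_levels, d)
        if P.sum() > 0:
            per_dir.append(glcm_features_single(P))
    if not per_dir:
        # single voxel: treat as a one-entry matrix at the observed level
        g = int(labels.max())
        P = np.zeros((n_levels, n_levels))
        P[g - 1, g - 1] = 1.0
        per_dir = [glcm_features_single(P)]
        degenerate = True
    else:
        degenerate = n_levels == 1
    out = OrderedDict((k, float(np.mean([f[k] for f in per_dir]))) for k in names)
    return out, degenerate
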