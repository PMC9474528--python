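"""First-order intensity statistics (18 features).

Intensity statistics use raw values; Entropy and Uniformity use the
fixed-bin-size discretised histogram. Moments are population moments.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

__all__ = ["first_order_features", "histogram_probabilities"]


def histogram_probabilities(labels_in_mask: np.ndarray, n_levels: int) -> np.ndarray:
    counts = np.bincount(labels_in_mask.astype(np.int64), minlength=n_levels + 1)[1:]
    return counts / counts.sum()


def first_order_features(
    values: np.ndarray,
    labels_in_mask: np.ndarray,
    n_levels: int,
    voxel_volume_mm3: float,
) -> "OrderedDict[str, float]":
    """18 first-order features from in-mask raw values and bin labels."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty region")
    p = histogram_probabilities(labels_in_mask, n_levels)
    nz = p[p > 0]
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    out: OrderedDict[str, float] = OrderedDict()
    out["Energy"] = float(np.sum(x**2))
    out["TotalEnergy"] = float(voxel_volume_mm3 * np.sum(x**2))
    out["Entropy"] = float(-np.sum(nz * np.log2(nz)))
    out["Minimum"] = float(x.min())
    out["10Percentile"] = float(p10)
    out["90Percentile"] = float(p90)
    out["Maximum"] = float(x.max())
    out["Mean"] = float(mean)
    out["Median"] = float(np.median(x))
    out["InterquartileRange"] = float(p75 - p25)
    out["Range"] = float(x.max() - x.min())
    out["MeanAbsoluteDeviation"] = float(np.abs(dev).mean())
    out["RobustMeanAbsoluteDeviation"] = rmad
    out["RootMeanSquared"] = float(np.sqrt(np.mean(x**2)))
    out["Skewness"] = float(m3 / m2**1.5) if m2 > 0 else 0.0
    out["Kurtosis"] = float(m4 / m2**2) if m2 > 0 else 0.0
    out["Variance"] = float(m2)
    out["Uniformity"] = float(np.sum(p**2))
    return out
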