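"""Shared helpers for the texture families."""

from __future__ import annotations

import numpy as np

# 13 unique 3-D directions at Chebyshev distance 1 (half of the 26-neighbourhood)
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

# full 26-neighbourhood
NEIGHBOURS_26 = [d for d in
                 [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
                 if d != (0, 0, 0)]


def shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """out[p] = arr[p + d], filled with `fill` beyond the edge."""
    out = np.full_like(arr, fill)
    src = tuple(slice(max(0, o), arr.shape[a] + min(0, o)) for a, o in enumerate(d))
    dst = tuple(slice(max(0, -o), arr.shape[a] - max(0, o)) for a, o in enumerate(d))
    out[dst] = arr[src]
    return out


def entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))
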