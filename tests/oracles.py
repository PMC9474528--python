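"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops (or a clearly
different algorithm) so that agreement with the vectorised package code is
a meaningful check, not a tautology.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

# 13 unique directions, duplicated from the implementation on purpose:
# the direction set is part of the convention under test.
DIRS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

N26 = [
    (i, j, k)
    for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def inside(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


# ------------------------------------------------------------------ GLCM

def glcm_matrix_oracle(labels, ng, d):
    P = np.zeros((ng, ng))
    shape = labels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                a = labels[x, y, z]
                if a == 0:
                    continue
                q = (x + d[0], y + d[1], z + d[2])
                if inside(shape, q):
                    b = labels[q]
                    if b > 0:
                        P[a - 1, b - 1] += 1
                        P[b - 1, a - 1] += 1  # symmetric
    s = P.sum()
    return P / s if s > 0 else P


def glcm_features_oracle(p):
    """Feature formulas evaluated with explicit loops."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))
    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    diff_avg = sum(k * v for k, v in pdiff.items())

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = ent(p.ravel())
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng) for j in range(ng)
        if px[i] * py[j] > 0
    )
    hx, hy = ent(px), ent(py)

    f = {}
    f["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    f["JointAverage"] = mux
    f["ClusterProminence"] = sum(
        (i + j + 2 - mux - muy) ** 4 * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["ClusterShade"] = sum(
        (i + j + 2 - mux - muy) ** 3 * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["ClusterTendency"] = sum(
        (i + j + 2 - mux - muy) ** 2 * p[i, j] for i in range(ng) for j in range(ng)
    )
    f["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    if sigx > 0 and sigy > 0:
        f["Correlation"] = (f["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0
    f["DifferenceAverage"] = diff_avg
    f["DifferenceEntropy"] = ent(pdiff.values())
    f["DifferenceVariance"] = sum((k - diff_avg) ** 2 * v for k, v in pdiff.items())
    f["JointEnergy"] = sum(p[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["JointEntropy"] = hxy
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0)))
    f["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    f["Idmn"] = sum(p[i, j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng))
    f["Id"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    f["Idn"] = sum(p[i, j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    f["InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["MaximumProbability"] = max(p[i, j] for i in range(ng) for j in range(ng))
    f["SumEntropy"] = ent(psum.values())
    f["SumSquares"] = sum((i + 1 - mux) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    return f


def glcm_averaged_oracle(labels, ng):
    per_dir = []
    for d in DIRS:
        P = glcm_matrix_oracle(labels, ng, d)
        if P.sum() > 0:
            per_dir.append(glcm_features_oracle(P))
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


# ----------------------------------------------------------------- GLRLM

def runs_oracle(labels, d):
    """Enumerate maximal runs by explicit line walking."""
    shape = labels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = labels[x, y, z]
                if g == 0:
                    continue
                prev = (x - d[0], y - d[1], z - d[2])
                if inside(shape, prev) and labels[prev] == g:
                    continue  # not a run start
                length = 1
                cur = (x + d[0], y + d[1], z + d[2])
                while inside(shape, cur) and labels[cur] == g:
                    length += 1
                    cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                runs.append((g, length))
    return runs


def glrlm_matrix_oracle(labels, ng, d):
    runs = runs_oracle(labels, d)
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((ng, max_len))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def rl_style_features_oracle(P, n_voxels, prefix_short, prefix_long, gl_prefix, length_name):
    """Shared run-length/size-zone/dependence feature formulas, loop style."""
    ng, nl = P.shape
    nr = P.sum()
    f = {}
    f[f"Short{prefix_short}Emphasis"] = sum(
        P[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / nr
    f[f"Long{prefix_long}Emphasis"] = sum(
        P[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / nr
    f["GrayLevelNonUniformity"] = sum(
        sum(P[i, j] for j in range(nl)) ** 2 for i in range(ng)
    ) / nr
    f[f"{length_name}NonUniformity"] = sum(
        sum(P[i, j] for i in range(ng)) ** 2 for j in range(nl)
    ) / nr
    mu_i = sum((i + 1) * P[i, j] / nr for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * P[i, j] / nr for i in range(ng) for j in range(nl))
    f["GrayLevelVariance"] = sum(
        (i + 1 - mu_i) ** 2 * P[i, j] / nr for i in range(ng) for j in range(nl)
    )
    f[f"{length_name}Variance"] = sum(
        (j + 1 - mu_j) ** 2 * P[i, j] / nr for i in range(ng) for j in range(nl)
    )
    f["Entropy"] = -sum(
        (P[i, j] / nr) * math.log2(P[i, j] / nr)
        for i in range(ng) for j in range(nl) if P[i, j] > 0
    )
    f[f"Low{gl_prefix}Emphasis"] = sum(
        P[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / nr
    f[f"High{gl_prefix}Emphasis"] = sum(
        P[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)
    ) / nr
    f["Percentage"] = nr / n_voxels
    f["Nr"] = nr
    return f


# ----------------------------------------------------------------- GLSZM

def zones_oracle(labels):
    """26-connected equal-level zones by explicit stack-based flood fill."""
    shape = labels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = labels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in N26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if inside(shape, q) and not seen[q] and labels[q] == g:
                            seen[q] = True
                            stack.append(q)
                zones.append((int(g), size))
    return zones


def glszm_matrix_oracle(labels, ng):
    zones = zones_oracle(labels)
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


# ----------------------------------------------------------------- NGTDM

def ngtdm_oracle(labels, ng):
    shape = labels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = labels[x, y, z]
                if g == 0:
                    continue
                nbrs = []
                for d in N26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if inside(shape, q) and labels[q] > 0:
                        nbrs.append(labels[q])
                if not nbrs:
                    continue
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    return n_i, s_i


def ngtdm_features_oracle(n_i, s_i):
    ng = len(n_i)
    N = n_i.sum()
    p = n_i / N
    pos = [i for i in range(ng) if p[i] > 0]
    ngp = len(pos)
    f = {}
    denom = sum(p[i] * s_i[i] for i in range(ng))
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        f["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in pos for j in pos)
            / (ngp * (ngp - 1))
            * sum(s_i) / N
        )
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in pos for j in pos)
        f["Busyness"] = denom / busy_den if busy_den > 0 else 0.0
        f["Complexity"] = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in pos for j in pos
        ) / N
        sum_s = sum(s_i)
        f["Strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in pos for j in pos) / sum_s
            if sum_s > 0 else 0.0
        )
    else:
        f.update({"Contrast": 0.0, "Busyness": 0.0, "Complexity": 0.0, "Strength": 0.0})
    return f


# ------------------------------------------------------------------ GLDM

def gldm_matrix_oracle(labels, ng):
    shape = labels.shape
    entries = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                g = labels[x, y, z]
                if g == 0:
                    continue
                dep = 1
                for d in N26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if inside(shape, q) and labels[q] == g:
                        dep += 1
                entries.append((int(g), dep))
    max_dep = max(d for _, d in entries)
    P = np.zeros((ng, max_dep))
    for g, d in entries:
        P[g - 1, d - 1] += 1
    return P


# ------------------------------------------------------------ first order

def first_order_oracle(values, labels_in_mask, n_levels, voxel_volume):
    xs = [float(v) for v in values]
    n = len(xs)
    counts = [0] * n_levels
    for l in labels_in_mask:
        counts[int(l) - 1] += 1
    probs = [c / n for c in counts]
    mean = sum(xs) / n
    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    p10, p25, p75, p90 = np.percentile(xs, [10, 25, 75, 90])
    robust = [v for v in xs if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    f = {}
    f["Energy"] = sum(v**2 for v in xs)
    f["TotalEnergy"] = voxel_volume * f["Energy"]
    f["Entropy"] = -sum(p * math.log2(p) for p in probs if p > 0)
    f["Minimum"] = min(xs)
    f["10Percentile"] = float(p10)
    f["90Percentile"] = float(p90)
    f["Maximum"] = max(xs)
    f["Mean"] = mean
    f["Median"] = float(np.median(xs))
    f["InterquartileRange"] = float(p75 - p25)
    f["Range"] = max(xs) - min(xs)
    f["MeanAbsoluteDeviation"] = sum(abs(v - mean) for v in xs) / n
    f["RobustMeanAbsoluteDeviation"] = sum(abs(v - rmean) for v in robust) / len(robust)
    f["RootMeanSquared"] = math.sqrt(f["Energy"] / n)
    f["Skewness"] = m3 / m2**1.5 if m2 > 0 else 0.0
    f["Kurtosis"] = m4 / m2**2 if m2 > 0 else 0.0
    f["Variance"] = m2
    f["Uniformity"] = sum(p**2 for p in probs)
    return f


# ------------------------------------------------------------------ misc

def sphere_members_oracle(shape, spacing, centre, radius):
    """All voxels whose centre lies within `radius` mm of `centre`'s centre."""
    out = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                d2 = (
                    ((x - centre[0]) * spacing[0]) ** 2
                    + ((y - centre[1]) * spacing[1]) ** 2
                    + ((z - centre[2]) * spacing[2]) ** 2
                )
                if d2 <= radius**2 + 1e-9:
                    out.append((x, y, z))
    return out


def flood_fill_oracle(binary, seed):
    """26-connected component of `binary` containing `seed` (BFS)."""
    comp = np.zeros(binary.shape, dtype=bool)
    if not binary[seed]:
        return comp
    stack = [seed]
    comp[seed] = True
    while stack:
        p = stack.pop()
        for d in N26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if inside(binary.shape, q) and binary[q] and not comp[q]:
                comp[q] = True
                stack.append(q)
    return comp


def auc_pairs_oracle(scores, is_pos):
    """AUC by exhaustive concordant/tied pair counting."""
    pos = [s for s, p in zip(scores, is_pos) if p]
    neg = [s for s, p in zip(scores, is_pos) if not p]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def kmo_oracle(R):
    """KMO with partial correlations obtained via regression residuals."""
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    r2 = 0.0
    q2 = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            r2 += R[i, j] ** 2
            q2 += partial_corr_oracle(R, i, j) ** 2
    if r2 == 0:
        return float("nan")
    return r2 / (r2 + q2)


def partial_corr_oracle(R, i, j):
    """Partial correlation of i, j given the rest, via the regression route.

    Treat R as a covariance of standardised variables; the partial
    correlation is the correlation of the residuals of i and j after
    regressing each on all other variables.
    """
    p = R.shape[0]
    others = [k for k in range(p) if k not in (i, j)]
    if not others:
        return R[i, j]
    Roo = R[np.ix_(others, others)]
    roi = R[np.ix_(others, [i])]
    roj = R[np.ix_(others, [j])]
    bi = np.linalg.solve(Roo, roi)
    bj = np.linalg.solve(Roo, roj)
    var_i = R[i, i] - (roi.T @ bi).item()
    var_j = R[j, j] - (roj.T @ bj).item()
    cov_ij = R[i, j] - (roi.T @ bj).item()
    return cov_ij / math.sqrt(var_i * var_j)
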