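"""Brute-force texture-feature oracles.

Every function here recomputes a texture-matrix family by *direct
enumeration* — explicit Python loops over voxel pairs, runs, zones and
neighborhoods, dict-based matrix accumulation, and scalar-loop feature
formulas.  They share the package's documented conventions (gray levels are
bin numbers, 13 directions with feature-then-average aggregation, N = n_bins
in Idmn/Idn, dependence size = dependent neighbors + 1) but none of its
vectorized machinery, so agreement checks the implementation path.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

EPS = float(np.spacing(1.0))

DIRS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

OFFS_26 = [(a, b, c)
           for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
           if (a, b, c) != (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= p[k] < shape[k] for k in range(3))


def _voi_voxels(labels):
    return [tuple(p) for p in np.argwhere(np.asarray(labels) > 0)]


# ---------------------------------------------------------------------------
# GLCM


def _glcm_counts(labels, direction):
    counts: dict[tuple[int, int], float] = {}
    labels = np.asarray(labels)
    for p in _voi_voxels(labels):
        q = (p[0] + direction[0], p[1] + direction[1], p[2] + direction[2])
        if _inside(labels.shape, q) and labels[q] > 0:
            i, j = int(labels[p]), int(labels[q])
            counts[(i, j)] = counts.get((i, j), 0.0) + 1.0
            counts[(j, i)] = counts.get((j, i), 0.0) + 1.0
    return counts


def _glcm_features_from_counts(counts, n_bins):
    total = sum(counts.values())
    P = {ij: c / total for ij, c in counts.items()}
    px: dict[int, float] = {}
    py: dict[int, float] = {}
    for (i, j), p in P.items():
        px[i] = px.get(i, 0.0) + p
        py[j] = py.get(j, 0.0) + p
    ux = sum(i * v for i, v in px.items())
    uy = sum(j * v for j, v in py.items())
    sigx = math.sqrt(sum((i - ux) ** 2 * v for i, v in px.items()))
    sigy = math.sqrt(sum((j - uy) ** 2 * v for j, v in py.items()))
    pdiff: dict[int, float] = {}
    psum: dict[int, float] = {}
    for (i, j), p in P.items():
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p
        psum[i + j] = psum.get(i + j, 0.0) + p

    joint_entropy = -sum(p * math.log2(p + EPS) for p in P.values())
    hx = -sum(v * math.log2(v + EPS) for v in px.values())
    hy = -sum(v * math.log2(v + EPS) for v in py.values())
    hxy1 = -sum(p * math.log2(px[i] * py[j] + EPS) for (i, j), p in P.items())
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j] + EPS)
                for i in px for j in py)
    max_h = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - joint_entropy)), 0.0))

    levels = sorted(px)
    if len(levels) < 2:
        mcc = 1.0
    else:
        q = np.zeros((len(levels), len(levels)))
        for a, i in enumerate(levels):
            for b, j in enumerate(levels):
                q[a, b] = sum(P.get((i, k), 0.0) * P.get((j, k), 0.0)
                              / (px[i] * py[k]) for k in levels)
        eig = sorted(np.linalg.eigvals(q).real, reverse=True)
        mcc = math.sqrt(max(eig[1], 0.0))

    da = sum(k * v for k, v in pdiff.items())
    corr_num = sum(i * j * p for (i, j), p in P.items()) - ux * uy
    return {
        "Autocorrelation": sum(i * j * p for (i, j), p in P.items()),
        "Cluster Prominence": sum((i + j - ux - uy) ** 4 * p
                                  for (i, j), p in P.items()),
        "Cluster Shade": sum((i + j - ux - uy) ** 3 * p
                             for (i, j), p in P.items()),
        "Cluster Tendency": sum((i + j - ux - uy) ** 2 * p
                                for (i, j), p in P.items()),
        "Contrast": sum((i - j) ** 2 * p for (i, j), p in P.items()),
        "Correlation": corr_num / (sigx * sigy) if sigx * sigy > 0 else 1.0,
        "Difference Average": da,
        "Difference Entropy": -sum(v * math.log2(v + EPS)
                                   for v in pdiff.values()),
        "Difference Variance": sum((k - da) ** 2 * v
                                   for k, v in pdiff.items()),
        "Id": sum(v / (1.0 + k) for k, v in pdiff.items()),
        "Idm": sum(v / (1.0 + k ** 2) for k, v in pdiff.items()),
        "Idmn": sum(v / (1.0 + (k / n_bins) ** 2) for k, v in pdiff.items()),
        "Idn": sum(v / (1.0 + k / n_bins) for k, v in pdiff.items()),
        "Imc1": imc1,
        "Imc2": imc2,
        "Inverse Variance": sum(v / k ** 2 for k, v in pdiff.items() if k > 0),
        "Joint Average": ux,
        "Joint Energy": sum(p ** 2 for p in P.values()),
        "Joint Entropy": joint_entropy,
        "MCC": mcc,
        "Maximum Probability": max(P.values()),
        "Sum Average": sum(k * v for k, v in psum.items()),
        "Sum Entropy": -sum(v * math.log2(v + EPS) for v in psum.values()),
        "Sum Squares": sum((i - ux) ** 2 * p for (i, j), p in P.items()),
    }


def glcm_oracle(labels, n_bins):
    per_dir = []
    for d in DIRS_13:
        counts = _glcm_counts(labels, d)
        if counts:
            per_dir.append(_glcm_features_from_counts(counts, n_bins))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_oracle(labels, direction):
    labels = np.asarray(labels)
    runs = []
    for p in _voi_voxels(labels):
        prev = (p[0] - direction[0], p[1] - direction[1], p[2] - direction[2])
        if (_inside(labels.shape, prev) and labels[prev] == labels[p]):
            continue                      # not a run start
        length = 1
        cur = p
        while True:
            nxt = (cur[0] + direction[0], cur[1] + direction[1],
                   cur[2] + direction[2])
            if _inside(labels.shape, nxt) and labels[nxt] == labels[p]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(labels[p]), length))
    return runs


def _glrlm_features_from_runs(runs, n_voxels):
    nr = float(len(runs))
    by_level: dict[int, float] = {}
    by_length: dict[int, float] = {}
    for i, j in runs:
        by_level[i] = by_level.get(i, 0.0) + 1.0
        by_length[j] = by_length.get(j, 0.0) + 1.0
    mu_i = sum(i for i, _ in runs) / nr
    mu_j = sum(j for _, j in runs) / nr
    counts: dict[tuple[int, int], float] = {}
    for r in runs:
        counts[r] = counts.get(r, 0.0) + 1.0
    return {
        "Gray Level Non-Uniformity": sum(v ** 2 for v in by_level.values()) / nr,
        "Gray Level Non-Uniformity Normalized":
            sum(v ** 2 for v in by_level.values()) / nr ** 2,
        "Gray Level Variance": sum((i - mu_i) ** 2 for i, _ in runs) / nr,
        "High Gray Level Run Emphasis": sum(i ** 2 for i, _ in runs) / nr,
        "Long Run Emphasis": sum(j ** 2 for _, j in runs) / nr,
        "Long Run High Gray Level Emphasis":
            sum(i ** 2 * j ** 2 for i, j in runs) / nr,
        "Long Run Low Gray Level Emphasis":
            sum(j ** 2 / i ** 2 for i, j in runs) / nr,
        "Low Gray Level Run Emphasis": sum(1.0 / i ** 2 for i, _ in runs) / nr,
        "Run Entropy": -sum((c / nr) * math.log2(c / nr + EPS)
                            for c in counts.values()),
        "Run Length Non-Uniformity":
            sum(v ** 2 for v in by_length.values()) / nr,
        "Run Length Non-Uniformity Normalized":
            sum(v ** 2 for v in by_length.values()) / nr ** 2,
        "Run Percentage": nr / n_voxels,
        "Run Variance": sum((j - mu_j) ** 2 for _, j in runs) / nr,
        "Short Run Emphasis": sum(1.0 / j ** 2 for _, j in runs) / nr,
        "Short Run High Gray Level Emphasis":
            sum(i ** 2 / j ** 2 for i, j in runs) / nr,
        "Short Run Low Gray Level Emphasis":
            sum(1.0 / (i ** 2 * j ** 2) for i, j in runs) / nr,
    }


def glrlm_oracle(labels, n_bins):
    n_vox = len(_voi_voxels(labels))
    per_dir = []
    for d in DIRS_13:
        runs = _runs_oracle(labels, d)
        if runs:
            per_dir.append(_glrlm_features_from_runs(runs, n_vox))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


# ---------------------------------------------------------------------------
# GLSZM


def _zones_oracle(labels):
    labels = np.asarray(labels)
    seen = set()
    zones = []
    for start in _voi_voxels(labels):
        if start in seen:
            continue
        level = int(labels[start])
        queue = deque([start])
        seen.add(start)
        size = 0
        while queue:
            p = queue.popleft()
            size += 1
            for off in OFFS_26:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if (q not in seen and _inside(labels.shape, q)
                        and labels[q] == level):
                    seen.add(q)
                    queue.append(q)
        zones.append((level, size))
    return zones


def glszm_oracle(labels, n_bins):
    zones = _zones_oracle(labels)
    n_vox = len(_voi_voxels(labels))
    nz = float(len(zones))
    by_level: dict[int, float] = {}
    by_size: dict[int, float] = {}
    counts: dict[tuple[int, int], float] = {}
    for i, j in zones:
        by_level[i] = by_level.get(i, 0.0) + 1.0
        by_size[j] = by_size.get(j, 0.0) + 1.0
        counts[(i, j)] = counts.get((i, j), 0.0) + 1.0
    mu_i = sum(i for i, _ in zones) / nz
    mu_j = sum(j for _, j in zones) / nz
    return {
        "Gray Level Non-Uniformity": sum(v ** 2 for v in by_level.values()) / nz,
        "Gray Level Non-Uniformity Normalized":
            sum(v ** 2 for v in by_level.values()) / nz ** 2,
        "Gray Level Variance": sum((i - mu_i) ** 2 for i, _ in zones) / nz,
        "High Gray Level Zone Emphasis": sum(i ** 2 for i, _ in zones) / nz,
        "Large Area Emphasis": sum(j ** 2 for _, j in zones) / nz,
        "Large Area High Gray Level Emphasis":
            sum(i ** 2 * j ** 2 for i, j in zones) / nz,
        "Large Area Low Gray Level Emphasis":
            sum(j ** 2 / i ** 2 for i, j in zones) / nz,
        "Low Gray Level Zone Emphasis": sum(1.0 / i ** 2 for i, _ in zones) / nz,
        "Size Zone Non-Uniformity": sum(v ** 2 for v in by_size.values()) / nz,
        "Size Zone Non-Uniformity Normalized":
            sum(v ** 2 for v in by_size.values()) / nz ** 2,
        "Small Area Emphasis": sum(1.0 / j ** 2 for _, j in zones) / nz,
        "Small Area High Gray Level Emphasis":
            sum(i ** 2 / j ** 2 for i, j in zones) / nz,
        "Small Area Low Gray Level Emphasis":
            sum(1.0 / (i ** 2 * j ** 2) for i, j in zones) / nz,
        "Zone Entropy": -sum((c / nz) * math.log2(c / nz + EPS)
                             for c in counts.values()),
        "Zone Percentage": nz / n_vox,
        "Zone Variance": sum((j - mu_j) ** 2 for _, j in zones) / nz,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_oracle(labels, n_bins, alpha=0):
    labels = np.asarray(labels)
    entries = []
    for p in _voi_voxels(labels):
        dep = 0
        for off in OFFS_26:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if (_inside(labels.shape, q) and labels[q] > 0
                    and abs(int(labels[q]) - int(labels[p])) <= alpha):
                dep += 1
        entries.append((int(labels[p]), dep + 1))
    nz = float(len(entries))
    by_level: dict[int, float] = {}
    by_dep: dict[int, float] = {}
    counts: dict[tuple[int, int], float] = {}
    for i, j in entries:
        by_level[i] = by_level.get(i, 0.0) + 1.0
        by_dep[j] = by_dep.get(j, 0.0) + 1.0
        counts[(i, j)] = counts.get((i, j), 0.0) + 1.0
    mu_i = sum(i for i, _ in entries) / nz
    mu_j = sum(j for _, j in entries) / nz
    return {
        "Dependence Entropy": -sum((c / nz) * math.log2(c / nz + EPS)
                                   for c in counts.values()),
        "Dependence Non-Uniformity": sum(v ** 2 for v in by_dep.values()) / nz,
        "Dependence Non-Uniformity Normalized":
            sum(v ** 2 for v in by_dep.values()) / nz ** 2,
        "Dependence Variance": sum((j - mu_j) ** 2 for _, j in entries) / nz,
        "Gray Level Non-Uniformity": sum(v ** 2 for v in by_level.values()) / nz,
        "Gray Level Variance": sum((i - mu_i) ** 2 for i, _ in entries) / nz,
        "High Gray Level Emphasis": sum(i ** 2 for i, _ in entries) / nz,
        "Large Dependence Emphasis": sum(j ** 2 for _, j in entries) / nz,
        "Large Dependence High Gray Level Emphasis":
            sum(i ** 2 * j ** 2 for i, j in entries) / nz,
        "Large Dependence Low Gray Level Emphasis":
            sum(j ** 2 / i ** 2 for i, j in entries) / nz,
        "Low Gray Level Emphasis": sum(1.0 / i ** 2 for i, _ in entries) / nz,
        "Small Dependence Emphasis": sum(1.0 / j ** 2 for _, j in entries) / nz,
        "Small Dependence High Gray Level Emphasis":
            sum(i ** 2 / j ** 2 for i, j in entries) / nz,
        "Small Dependence Low Gray Level Emphasis":
            sum(1.0 / (i ** 2 * j ** 2) for i, j in entries) / nz,
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_oracle(labels, n_bins):
    labels = np.asarray(labels)
    s: dict[int, float] = {}
    n: dict[int, float] = {}
    for p in _voi_voxels(labels):
        vals = []
        for off in OFFS_26:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if _inside(labels.shape, q) and labels[q] > 0:
                vals.append(int(labels[q]))
        if not vals:
            continue
        i = int(labels[p])
        s[i] = s.get(i, 0.0) + abs(i - sum(vals) / len(vals))
        n[i] = n.get(i, 0.0) + 1.0
    nvp = sum(n.values())
    p_i = {i: c / nvp for i, c in n.items()}
    present = sorted(p_i)
    ngp = len(present)
    sum_ps = sum(p_i[i] * s[i] for i in present)
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1))) * sum(s.values()) / nvp
        busy_den = sum(abs(i * p_i[i] - j * p_i[j])
                       for i in present for j in present)
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(i - j) * (p_i[i] * s[i] + p_i[j] * s[j])
                         / (p_i[i] + p_i[j])
                         for i in present for j in present) / nvp
        s_sum = sum(s.values())
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


ORACLES = {
    "glcm": glcm_oracle,
    "gldm": gldm_oracle,
    "glrlm": glrlm_oracle,
    "glszm": glszm_oracle,
    "ngtdm": ngtdm_oracle,
}
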