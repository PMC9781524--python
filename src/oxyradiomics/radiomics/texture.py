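"""3D gray-level texture features (75 features over five matrix families).

All families operate on the discretized VOI: gray levels are bin numbers
1..n_bins (empty bins keep their index; level *values* enter the formulas,
so empty levels contribute nothing to weighted sums).  Conventions:

* GLCM / GLRLM: distance 1, the 13 unique 3D directions, symmetric matrices,
  features computed per direction and then averaged (directions with no
  voxel pairs are skipped).
* GLSZM: zones are 26-connected components of equal gray level
  (direction-free, no averaging).
* GLDM: a neighbor is dependent if its level differs from the center by at
  most ``alpha`` (default 0); the dependence size recorded for a voxel is
  the dependent-neighbor count + 1 (the center itself), so sizes start at 1.
* NGTDM: each voxel is compared with the average level of its valid
  26-neighbors; voxels with no valid neighbor are excluded.

Where a ratio degenerates (single gray level, zero denominator) the
documented fallbacks of the reference radiomics literature are used:
GLCM Correlation of a zero-variance VOI is 1, NGTDM Coarseness is capped at
1e6, Busyness/Strength/Contrast fall back to 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVOI

_EPS = np.spacing(1.0)

#: 13 unique direction vectors of the 26-neighborhood (antipodes removed).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: all 26 neighbor offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
)


def _shifted(labels: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Array with value labels[v + off] at position v (0 where off-grid)."""
    out = np.zeros_like(labels)
    src, dst = [], []
    for d, n in zip(off, labels.shape):
        if d >= 0:
            dst.append(slice(0, n - d))
            src.append(slice(d, n))
        else:
            dst.append(slice(-d, n))
            src.append(slice(0, n + d))
    out[tuple(dst)] = labels[tuple(src)]
    return out


def _pairs(labels: np.ndarray, off: tuple[int, int, int]
           ) -> tuple[np.ndarray, np.ndarray]:
    """Center/neighbor label pairs where both endpoints are in the VOI."""
    nb = _shifted(labels, off)
    m = (labels > 0) & (nb > 0)
    return labels[m], nb[m]


# ---------------------------------------------------------------------------
# GLCM


def _glcm_matrix(labels: np.ndarray, n_bins: int,
                 off: tuple[int, int, int]) -> np.ndarray:
    c, nb = _pairs(labels, off)
    if c.size == 0:
        return np.zeros((n_bins, n_bins))
    mat = np.zeros((n_bins, n_bins))
    np.add.at(mat, (c - 1, nb - 1), 1.0)
    return mat + mat.T          # symmetric: count both (i,j) and (j,i)


def _glcm_features_single(P: np.ndarray, n_bins: int) -> dict[str, float]:
    """The 24 co-occurrence features of one normalized symmetric GLCM."""
    N = n_bins
    i = np.arange(1, N + 1, dtype=np.float64)
    ii = i[:, None] * np.ones((1, N))
    jj = ii.T
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sigx = float(np.sqrt(np.sum((i - ux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((i - uy) ** 2 * py)))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, N, dtype=np.float64)
    pd = np.zeros(N)
    np.add.at(pd, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * N + 1, dtype=np.float64)
    ps = np.zeros(2 * N - 1)
    np.add.at(ps, (ii + jj).astype(int).ravel() - 2, P.ravel())

    nz = P > 0
    joint_entropy = float(-np.sum(P[nz] * np.log2(P[nz] + _EPS)))
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0] + _EPS)))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0] + _EPS)))
    pxpy = px[:, None] * py[None, :]
    hxy1 = float(-np.sum(P[nz] * np.log2(pxpy[nz] + _EPS)))
    nz2 = pxpy > 0
    hxy2 = float(-np.sum(pxpy[nz2] * np.log2(pxpy[nz2] + _EPS)))

    max_h = max(hx, hy)
    imc1 = (joint_entropy - hxy1) / max_h if max_h > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    # maximal correlation coefficient on the present-level submatrix
    present = np.flatnonzero(px > 0)
    if present.size < 2:
        mcc = 1.0
    else:
        Ps = P[np.ix_(present, present)]
        pxs = px[present]
        pys = py[present]
        A = Ps / pxs[:, None]
        C = Ps / pys[None, :]
        Q = A @ C.T
        eig = np.sort(np.linalg.eigvals(Q).real)[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0)))

    corr_num = float(np.sum(ii * jj * P)) - ux * uy
    da = float(np.sum(k_diff * pd))
    pd_nz = pd > 0
    ps_nz = ps > 0
    return {
        "Autocorrelation": float(np.sum(ii * jj * P)),
        "Cluster Prominence": float(np.sum((ii + jj - ux - uy) ** 4 * P)),
        "Cluster Shade": float(np.sum((ii + jj - ux - uy) ** 3 * P)),
        "Cluster Tendency": float(np.sum((ii + jj - ux - uy) ** 2 * P)),
        "Contrast": float(np.sum((ii - jj) ** 2 * P)),
        "Correlation": (corr_num / (sigx * sigy) if sigx * sigy > 0 else 1.0),
        "Difference Average": da,
        "Difference Entropy": float(-np.sum(pd[pd_nz] * np.log2(pd[pd_nz] + _EPS))),
        "Difference Variance": float(np.sum((k_diff - da) ** 2 * pd)),
        "Id": float(np.sum(pd / (1.0 + k_diff))),
        "Idm": float(np.sum(pd / (1.0 + k_diff ** 2))),
        "Idmn": float(np.sum(pd / (1.0 + (k_diff / N) ** 2))),
        "Idn": float(np.sum(pd / (1.0 + k_diff / N))),
        "Imc1": imc1,
        "Imc2": imc2,
        "Inverse Variance": float(np.sum(pd[1:] / k_diff[1:] ** 2)),
        "Joint Average": ux,
        "Joint Energy": float(np.sum(P ** 2)),
        "Joint Entropy": joint_entropy,
        "MCC": mcc,
        "Maximum Probability": float(P.max()),
        "Sum Average": float(np.sum(k_sum * ps)),
        "Sum Entropy": float(-np.sum(ps[ps_nz] * np.log2(ps[ps_nz] + _EPS))),
        "Sum Squares": float(np.sum((ii - ux) ** 2 * P)),
    }


def glcm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """24 GLCM features, averaged over the 13 distance-1 directions."""
    labels = voi.labels
    per_dir: list[dict[str, float]] = []
    for off in DIRECTIONS_13:
        mat = _glcm_matrix(labels, voi.n_bins, off)
        total = mat.sum()
        if total == 0:
            continue
        per_dir.append(_glcm_features_single(mat / total, voi.n_bins))
    if not per_dir:
        # single-voxel VOI: treat as one certain co-occurrence of the lone
        # level with itself (documented degenerate rule)
        lvl = int(voi.voi_labels[0])
        P = np.zeros((voi.n_bins, voi.n_bins))
        P[lvl - 1, lvl - 1] = 1.0
        per_dir.append(_glcm_features_single(P, voi.n_bins))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_along(labels: np.ndarray, off: tuple[int, int, int]
                ) -> tuple[np.ndarray, np.ndarray]:
    """(level, length) of every maximal run along direction ``off``."""
    coords = np.argwhere(labels > 0)
    if coords.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    vals = labels[labels > 0]
    d = np.asarray(off)
    axis0 = int(np.flatnonzero(d)[0])       # first nonzero component (= +1)
    t = coords[:, axis0]
    line = coords - t[:, None] * d[None, :]     # constant along the line
    # lexicographic sort by (line, t)
    enc_base = max(labels.shape) * 3
    line_key = ((line[:, 0] + enc_base) * (4 * enc_base ** 2)
                + (line[:, 1] + enc_base) * (2 * enc_base)
                + (line[:, 2] + enc_base))
    order = np.lexsort((t, line_key))
    lk, ts, vs = line_key[order], t[order], vals[order]
    # a new run starts where the line changes, positions skip, or level changes
    new_run = np.ones(len(order), dtype=bool)
    new_run[1:] = (lk[1:] != lk[:-1]) | (ts[1:] != ts[:-1] + 1) | (vs[1:] != vs[:-1])
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, len(order)))
    return vs[starts], lengths


def _weighted_level_stats(mat: np.ndarray, i: np.ndarray, j: np.ndarray
                          ) -> tuple[float, float, float, float]:
    """(mean_i, var_i, mean_j, var_j) of the normalized matrix."""
    p = mat / mat.sum()
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(i * pi))
    mu_j = float(np.sum(j * pj))
    return (mu_i, float(np.sum((i - mu_i) ** 2 * pi)),
            mu_j, float(np.sum((j - mu_j) ** 2 * pj)))


def _glrlm_features_single(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ii = i[:, None]
    jj = j[None, :]
    ri = mat.sum(axis=1)
    rj = mat.sum(axis=0)
    p = mat / nr
    mu_i, var_i, mu_j, var_j = _weighted_level_stats(mat, i, j)
    pnz = p[p > 0]
    return {
        "Gray Level Non-Uniformity": float(np.sum(ri ** 2) / nr),
        "Gray Level Non-Uniformity Normalized": float(np.sum(ri ** 2) / nr ** 2),
        "Gray Level Variance": var_i,
        "High Gray Level Run Emphasis": float(np.sum(mat * ii ** 2) / nr),
        "Long Run Emphasis": float(np.sum(mat * jj ** 2) / nr),
        "Long Run High Gray Level Emphasis": float(np.sum(mat * ii ** 2 * jj ** 2) / nr),
        "Long Run Low Gray Level Emphasis": float(np.sum(mat * jj ** 2 / ii ** 2) / nr),
        "Low Gray Level Run Emphasis": float(np.sum(mat / ii ** 2) / nr),
        "Run Entropy": float(-np.sum(pnz * np.log2(pnz + _EPS))),
        "Run Length Non-Uniformity": float(np.sum(rj ** 2) / nr),
        "Run Length Non-Uniformity Normalized": float(np.sum(rj ** 2) / nr ** 2),
        "Run Percentage": float(nr / n_voxels),
        "Run Variance": var_j,
        "Short Run Emphasis": float(np.sum(mat / jj ** 2) / nr),
        "Short Run High Gray Level Emphasis": float(np.sum(mat * ii ** 2 / jj ** 2) / nr),
        "Short Run Low Gray Level Emphasis": float(np.sum(mat / (ii ** 2 * jj ** 2)) / nr),
    }


def glrlm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    labels = voi.labels
    n_vox = voi.n_voxels
    max_len = max(labels.shape)
    per_dir = []
    for off in DIRECTIONS_13:
        levels, lengths = _runs_along(labels, off)
        if levels.size == 0:
            continue
        mat = np.zeros((voi.n_bins, max_len))
        np.add.at(mat, (levels - 1, lengths - 1), 1.0)
        per_dir.append(_glrlm_features_single(mat, n_vox))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


def _glszm_matrix(voi: DiscretizedVOI) -> np.ndarray:
    """Zone matrix Z[level-1, size-1]: 26-connected equal-level components."""
    # crop to the VOI bounding box to keep component labeling cheap
    idx = np.argwhere(voi.voi_mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = voi.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = voi.n_voxels
    mat = np.zeros((voi.n_bins, max_size))
    for lvl in np.unique(sub[sub > 0]):
        comp, n_comp = ndimage.label(sub == lvl, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        np.add.at(mat, (lvl - 1, sizes - 1), 1.0)
    last = int(np.max(np.flatnonzero(mat.sum(axis=0) > 0))) + 1
    return mat[:, :last]


def glszm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """16 size-zone features (direction-free)."""
    mat = _glszm_matrix(voi)
    nz = mat.sum()
    n_vox = voi.n_voxels
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ii = i[:, None]
    jj = j[None, :]
    zi = mat.sum(axis=1)
    zj = mat.sum(axis=0)
    p = mat / nz
    mu_i, var_i, mu_j, var_j = _weighted_level_stats(mat, i, j)
    pnz = p[p > 0]
    return {
        "Gray Level Non-Uniformity": float(np.sum(zi ** 2) / nz),
        "Gray Level Non-Uniformity Normalized": float(np.sum(zi ** 2) / nz ** 2),
        "Gray Level Variance": var_i,
        "High Gray Level Zone Emphasis": float(np.sum(mat * ii ** 2) / nz),
        "Large Area Emphasis": float(np.sum(mat * jj ** 2) / nz),
        "Large Area High Gray Level Emphasis": float(np.sum(mat * ii ** 2 * jj ** 2) / nz),
        "Large Area Low Gray Level Emphasis": float(np.sum(mat * jj ** 2 / ii ** 2) / nz),
        "Low Gray Level Zone Emphasis": float(np.sum(mat / ii ** 2) / nz),
        "Size Zone Non-Uniformity": float(np.sum(zj ** 2) / nz),
        "Size Zone Non-Uniformity Normalized": float(np.sum(zj ** 2) / nz ** 2),
        "Small Area Emphasis": float(np.sum(mat / jj ** 2) / nz),
        "Small Area High Gray Level Emphasis": float(np.sum(mat * ii ** 2 / jj ** 2) / nz),
        "Small Area Low Gray Level Emphasis": float(np.sum(mat / (ii ** 2 * jj ** 2)) / nz),
        "Zone Entropy": float(-np.sum(pnz * np.log2(pnz + _EPS))),
        "Zone Percentage": float(nz / n_vox),
        "Zone Variance": var_j,
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(voi: DiscretizedVOI, alpha: int = 0) -> dict[str, float]:
    """14 dependence features (26-neighborhood, |Δlevel| <= alpha)."""
    labels = voi.labels
    in_voi = labels > 0
    dep = np.zeros(labels.shape, dtype=np.int64)
    for off in OFFSETS_26:
        nb = _shifted(labels, off)
        dep += (in_voi & (nb > 0)
                & (np.abs(nb - labels) <= alpha)).astype(np.int64)
    sizes = dep[in_voi] + 1       # dependence size includes the center voxel
    levels = labels[in_voi]
    mat = np.zeros((voi.n_bins, 27))
    np.add.at(mat, (levels - 1, sizes - 1), 1.0)

    nz = mat.sum()                # == number of VOI voxels
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    ii = i[:, None]
    jj = j[None, :]
    di = mat.sum(axis=1)
    dj = mat.sum(axis=0)
    p = mat / nz
    mu_i, var_i, mu_j, var_j = _weighted_level_stats(mat, i, j)
    pnz = p[p > 0]
    return {
        "Dependence Entropy": float(-np.sum(pnz * np.log2(pnz + _EPS))),
        "Dependence Non-Uniformity": float(np.sum(dj ** 2) / nz),
        "Dependence Non-Uniformity Normalized": float(np.sum(dj ** 2) / nz ** 2),
        "Dependence Variance": var_j,
        "Gray Level Non-Uniformity": float(np.sum(di ** 2) / nz),
        "Gray Level Variance": var_i,
        "High Gray Level Emphasis": float(np.sum(mat * ii ** 2) / nz),
        "Large Dependence Emphasis": float(np.sum(mat * jj ** 2) / nz),
        "Large Dependence High Gray Level Emphasis": float(np.sum(mat * ii ** 2 * jj ** 2) / nz),
        "Large Dependence Low Gray Level Emphasis": float(np.sum(mat * jj ** 2 / ii ** 2) / nz),
        "Low Gray Level Emphasis": float(np.sum(mat / ii ** 2) / nz),
        "Small Dependence Emphasis": float(np.sum(mat / jj ** 2) / nz),
        "Small Dependence High Gray Level Emphasis": float(np.sum(mat * ii ** 2 / jj ** 2) / nz),
        "Small Dependence Low Gray Level Emphasis": float(np.sum(mat / (ii ** 2 * jj ** 2)) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM

#: cap applied to Coarseness when the weighted-difference sum is zero
COARSENESS_CAP = 1e6


def ngtdm_features(voi: DiscretizedVOI) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    labels = voi.labels.astype(np.float64)
    in_voi = voi.labels > 0
    nbr_sum = np.zeros_like(labels)
    nbr_cnt = np.zeros_like(labels)
    for off in OFFSETS_26:
        nb = _shifted(voi.labels, off)
        nbr_sum += nb
        nbr_cnt += (nb > 0).astype(np.float64)
    has_nbr = in_voi & (nbr_cnt > 0)
    diff = np.zeros_like(labels)
    np.divide(nbr_sum, nbr_cnt, out=diff, where=has_nbr)
    abs_diff = np.abs(labels - diff)

    lv = voi.labels[has_nbr]
    s = np.zeros(voi.n_bins)
    np.add.at(s, lv - 1, abs_diff[has_nbr])
    n_i = np.bincount(lv, minlength=voi.n_bins + 1)[1:].astype(np.float64)
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("no VOI voxel has a valid neighbor")
    p_i = n_i / nvp

    present = np.flatnonzero(n_i > 0)
    ngp = present.size
    i_vals = (present + 1).astype(np.float64)
    p_p = p_i[present]
    s_p = s[present]

    sum_ps = float(np.sum(p_p * s_p))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else COARSENESS_CAP

    if ngp > 1:
        dmat = (i_vals[:, None] - i_vals[None, :]) ** 2
        contrast = (float(np.sum(p_p[:, None] * p_p[None, :] * dmat))
                    / (ngp * (ngp - 1))) * float(s_p.sum()) / nvp
        ipi = i_vals * p_p
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        absdiff = np.abs(i_vals[:, None] - i_vals[None, :])
        num = (p_p[:, None] * s_p[:, None] + p_p[None, :] * s_p[None, :])
        den = p_p[:, None] + p_p[None, :]
        complexity = float(np.sum(absdiff * num / den)) / nvp
        s_sum = float(s_p.sum())
        strength = (float(np.sum((p_p[:, None] + p_p[None, :]) * dmat)) / s_sum
                    if s_sum > 0 else 0.0)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
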