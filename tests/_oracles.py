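"""Independent brute-force oracles used by the texture and segmentation tests.

Everything here is written as plain explicit enumeration (python loops over
voxels, pairs, runs and zones) so it shares no code path with the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _in_bounds(p, shape):
    return all(0 <= p[a] < shape[a] for a in range(3))


def glcm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Merged symmetric co-occurrence counts: every ordered in-mask pair at
    distance 1 over the 26-neighbourhood (equivalent to symmetrizing the 13
    unique directions)."""
    mat = np.zeros((n_levels, n_levels))
    for p in np.argwhere(mask):
        for d in OFFSETS_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in_bounds(q, mask.shape) and mask[q]:
                mat[levels[tuple(p)] - 1, levels[q] - 1] += 1
    return mat


def ngldm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level |level - neighbourhood mean| sums and voxel counts."""
    s = np.zeros(n_levels)
    counts = np.zeros(n_levels)
    for p in np.argwhere(mask):
        nb = []
        for d in OFFSETS_26:
            q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
            if _in_bounds(q, mask.shape) and mask[q]:
                nb.append(levels[q])
        if not nb:
            continue
        g = levels[tuple(p)]
        s[g - 1] += abs(g - sum(nb) / len(nb))
        counts[g - 1] += 1
    return s, counts


def glrlm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Run-length counts along one direction by explicit run walking."""
    runs = []
    for p in np.argwhere(mask):
        prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
        if (
            _in_bounds(prev, mask.shape)
            and mask[prev]
            and levels[prev] == levels[tuple(p)]
        ):
            continue
        g = levels[tuple(p)]
        length = 1
        cur = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
        while _in_bounds(cur, mask.shape) and mask[cur] and levels[cur] == g:
            length += 1
            cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
        runs.append((g, length))
    max_run = max((l for _, l in runs), default=1)
    mat = np.zeros((n_levels, max_run))
    for g, l in runs:
        mat[g - 1, l - 1] += 1
    return mat


def glzlm_brute(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts by flood fill over 26-connected equal-level components."""
    visited = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        g = levels[start]
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in OFFSETS_26:
                q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                if (
                    _in_bounds(q, mask.shape)
                    and mask[q]
                    and not visited[q]
                    and levels[q] == g
                ):
                    visited[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_zone = max((s for _, s in zones), default=1)
    mat = np.zeros((n_levels, max_zone))
    for g, size in zones:
        mat[g - 1, size - 1] += 1
    return mat


def glcm_features_brute(mat: np.ndarray) -> dict[str, float]:
    """The six co-occurrence statistics computed by scalar accumulation."""
    total = mat.sum()
    p = mat / total
    L = p.shape[0]
    homogeneity = energy = contrast = entropy = dissimilarity = 0.0
    mu_i = mu_j = 0.0
    for i in range(L):
        for j in range(L):
            mu_i += (i + 1) * p[i, j]
            mu_j += (j + 1) * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(L):
        for j in range(L):
            pij = p[i, j]
            homogeneity += pij / (1 + abs(i - j))
            energy += pij**2
            contrast += (i - j) ** 2 * pij
            dissimilarity += abs(i - j) * pij
            if pij > 0:
                entropy -= pij * np.log2(pij)
            var_i += (i + 1 - mu_i) ** 2 * pij
            var_j += (j + 1 - mu_j) ** 2 * pij
            cov += (i + 1 - mu_i) * (j + 1 - mu_j) * pij
    correlation = cov / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else float("nan")
    return {
        "glcm_homogeneity": homogeneity,
        "glcm_energy": energy,
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_entropy": entropy,
        "glcm_dissimilarity": dissimilarity,
    }


def ngldm_features_brute(s: np.ndarray, counts: np.ndarray) -> dict[str, float]:
    n = counts.sum()
    p = counts / n
    occupied = [i for i in range(len(p)) if p[i] > 0]
    ng = len(occupied)
    ps = sum(p[i] * s[i] for i in range(len(p)))
    coarseness = 1.0 / ps if ps > 0 else float("nan")
    if ng > 1:
        acc = 0.0
        for i in occupied:
            for j in occupied:
                acc += p[i] * p[j] * (i - j) ** 2
        contrast = acc / (ng * (ng - 1)) * (s.sum() / n)
        denom = 0.0
        for i in occupied:
            for j in occupied:
                denom += abs((i + 1) * p[i] - (j + 1) * p[j])
        busyness = ps / denom if denom > 0 else float("nan")
    else:
        contrast = busyness = float("nan")
    return {"ngldm_coarseness": coarseness, "ngldm_contrast": contrast, "ngldm_busyness": busyness}


def rlm_features_brute(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 11 run/zone statistics, generic names keyed by formula."""
    nr = mat.sum()
    L, maxlen = mat.shape
    acc = {k: 0.0 for k in (
        "short", "long", "lowgrey", "highgrey", "short_low", "short_high",
        "long_low", "long_high")}
    for i in range(L):
        for l in range(maxlen):
            r = mat[i, l]
            if r == 0:
                continue
            gi, ll = i + 1, l + 1
            acc["short"] += r / ll**2
            acc["long"] += r * ll**2
            acc["lowgrey"] += r / gi**2
            acc["highgrey"] += r * gi**2
            acc["short_low"] += r / (gi**2 * ll**2)
            acc["short_high"] += r * gi**2 / ll**2
            acc["long_low"] += r * ll**2 / gi**2
            acc["long_high"] += r * gi**2 * ll**2
    out = {k: v / nr for k, v in acc.items()}
    out["grey_nonuniformity"] = sum(mat[i, :].sum() ** 2 for i in range(L)) / nr
    out["length_nonuniformity"] = sum(mat[:, l].sum() ** 2 for l in range(maxlen)) / nr
    out["percentage"] = nr / n_voxels
    return out


RLM_KEYMAP_GLRLM = {
    "short": "glrlm_sre", "long": "glrlm_lre", "lowgrey": "glrlm_lgre",
    "highgrey": "glrlm_hgre", "short_low": "glrlm_srlge", "short_high": "glrlm_srhge",
    "long_low": "glrlm_lrlge", "long_high": "glrlm_lrhge",
    "grey_nonuniformity": "glrlm_glnu", "length_nonuniformity": "glrlm_rlnu",
    "percentage": "glrlm_rp",
}
RLM_KEYMAP_GLZLM = {
    "short": "glzlm_sze", "long": "glzlm_lze", "lowgrey": "glzlm_lgze",
    "highgrey": "glzlm_hgze", "short_low": "glzlm_szlge", "short_high": "glzlm_szhge",
    "long_low": "glzlm_lzlge", "long_high": "glzlm_lzhge",
    "grey_nonuniformity": "glzlm_glnu", "length_nonuniformity": "glzlm_zlnu",
    "percentage": "glzlm_zp",
}


def nestle_brute(data: np.ndarray, voi: np.ndarray, background: np.ndarray):
    """Two-pass explicit-enumeration adaptive threshold: (threshold, mask)."""
    voi_vals = [data[tuple(p)] for p in np.argwhere(voi)]
    vmax = max(voi_vals)
    hot = [v for v in voi_vals if v > 0.7 * vmax]
    hot_mean = sum(hot) / len(hot)
    bg_vals = [data[tuple(p)] for p in np.argwhere(background)]
    bg_mean = sum(bg_vals) / len(bg_vals)
    threshold = 0.3 * hot_mean + bg_mean
    mask = np.zeros(voi.shape, dtype=bool)
    for p in np.argwhere(voi):
        if data[tuple(p)] >= threshold:
            mask[tuple(p)] = True
    return threshold, mask
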