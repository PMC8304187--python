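"""Radiomic feature extraction for segmented PET tumors.

Computes the 41 imaging parameters of a tumor VOI: 4 conventional parameters
(maximum SUV, peak SUV, metabolic tumor volume, total lesion glycolysis),
6 first-order features (histogram skewness, kurtosis, entropy, energy and the
shape features sphericity and compacity) and 31 higher-order texture features
(6 GLCM, 3 NGLDM, 11 GLRLM, 11 GLZLM) after resampling the SUV range of the
lesion into 64 relative grey levels between zero and the lesion maximum.

Conventions
-----------
* Discretization: level(v) = min(L, floor(v / max * L) + 1), i.e. left-closed
  bins of width max/L on [0, max] with the top value clamped into bin L.
* GLCM: co-occurrences over the 13 unique 3D directions at distance 1,
  symmetrized, summed into one matrix before normalization (a per-direction
  averaged mode is available via ``glcm_mode="average"``).
* GLRLM: runs counted per direction; the 11 run statistics are computed per
  direction and averaged over the 13 directions.
* GLZLM: zones are 26-connected components of constant grey level.
* Entropies are reported in bits (log base 2).
* Degenerate statistics (e.g. GLCM correlation of a single-level lesion)
  are returned as NaN — an explicit missing marker, never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume import SUVVolume

__all__ = [
    "DiscretizedVOI",
    "TextureMatrices",
    "FeatureVector",
    "FEATURE_NAMES",
    "CONVENTIONAL_NAMES",
    "FIRST_ORDER_NAMES",
    "HIGHER_ORDER_NAMES",
    "discretize",
    "conventional_params",
    "first_order_features",
    "build_texture_matrices",
    "higher_order_features",
    "extract_all",
]

MIN_TUMOR_VOXELS = 64  # lesions below this size are excluded from radiomic analysis

# The 13 unique direction vectors of a 3D neighbourhood at distance 1
# (one representative per +/- pair of the 26 neighbours).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

CONVENTIONAL_NAMES = ("suv_max", "suv_peak", "mtv_cm3", "tlg_g")
FIRST_ORDER_NAMES = (
    "firstorder_skewness", "firstorder_kurtosis", "firstorder_entropy",
    "firstorder_energy", "shape_sphericity", "shape_compacity",
)
GLCM_NAMES = (
    "glcm_homogeneity", "glcm_energy", "glcm_contrast",
    "glcm_correlation", "glcm_entropy", "glcm_dissimilarity",
)
NGLDM_NAMES = ("ngldm_coarseness", "ngldm_contrast", "ngldm_busyness")
GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre",
    "glrlm_srlge", "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge",
    "glrlm_glnu", "glrlm_rlnu", "glrlm_rp",
)
GLZLM_NAMES = (
    "glzlm_sze", "glzlm_lze", "glzlm_lgze", "glzlm_hgze",
    "glzlm_szlge", "glzlm_szhge", "glzlm_lzlge", "glzlm_lzhge",
    "glzlm_glnu", "glzlm_zlnu", "glzlm_zp",
)
HIGHER_ORDER_NAMES = GLCM_NAMES + NGLDM_NAMES + GLRLM_NAMES + GLZLM_NAMES
FEATURE_NAMES = CONVENTIONAL_NAMES + FIRST_ORDER_NAMES + HIGHER_ORDER_NAMES
assert len(FEATURE_NAMES) == 41


@dataclass(frozen=True)
class DiscretizedVOI:
    """Integer grey levels (1..n_levels) of the tumor voxels on the full grid.

    ``levels`` is 0 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    suv_min: float
    suv_max: float

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass(frozen=True)
class TextureMatrices:
    """Raw (unnormalized) texture matrices of a discretized lesion.

    glcm : (L, L) symmetric co-occurrence counts summed over 13 directions
    ngldm_s : length-L sum of |level - neighbourhood mean| per grey level
    ngldm_counts : length-L voxel counts entering the NGLDM statistics
    glrlm : tuple of 13 per-direction run-length count matrices (L, max_run)
    glzlm : (L, max_zone) zone-size counts for 26-connected iso-level zones
    n_voxels : number of lesion voxels
    """

    glcm: np.ndarray
    ngldm_s: np.ndarray
    ngldm_counts: np.ndarray
    glrlm: tuple[np.ndarray, ...]
    glzlm: np.ndarray
    n_voxels: int


class FeatureVector(dict):
    """The 41 named imaging parameters of one tumor (an ordered mapping)."""

    def __init__(self, values: dict[str, float]):
        missing = set(FEATURE_NAMES) - set(values)
        extra = set(values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature vector mismatch: missing {missing}, extra {extra}")
        super().__init__({name: float(values[name]) for name in FEATURE_NAMES})


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray, pad: int = 0):
    idx = np.argwhere(mask)
    lo = idx.min(axis=0) - pad
    hi = idx.max(axis=0) + 1 + pad
    lo = np.maximum(lo, 0)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


def discretize(volume: SUVVolume, tumor_mask: np.ndarray, levels: int = 64) -> DiscretizedVOI:
    """Resample tumor SUVs into `levels` relative grey levels on [0, lesion max].

    level(v) = min(levels, floor(v / max * levels) + 1); zero maps to level 1
    and the lesion maximum maps to level `levels`.
    """
    if levels < 2:
        raise ValueError(f"need at least 2 grey levels, got {levels}")
    tumor_mask = volume.check_mask(tumor_mask, "tumor mask")
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    values = volume.data[tumor_mask]
    vmax = float(values.max())
    if vmax <= 0:
        raise ValueError("tumor has zero uptake everywhere; relative binning is undefined")
    lv = np.zeros(volume.shape, dtype=np.int32)
    lv[tumor_mask] = np.minimum(levels, np.floor(values / vmax * levels).astype(np.int64) + 1)
    return DiscretizedVOI(levels=lv, mask=tumor_mask, n_levels=levels, suv_min=0.0, suv_max=vmax)


def conventional_params(volume: SUVVolume, tumor_mask: np.ndarray) -> dict[str, float]:
    """Maximum SUV, peak SUV, MTV (cm^3) and TLG (g) of the lesion.

    Peak SUV is the mean SUV within a 1 cm^3 sphere (radius ~6.2 mm) centred
    on the hottest lesion voxel, over all volume voxels whose centres fall
    inside the sphere.
    """
    tumor_mask = volume.check_mask(tumor_mask, "tumor mask")
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    values = volume.data[tumor_mask]
    suv_max = float(values.max())

    # hottest lesion voxel (first in scan order on ties)
    masked = np.where(tumor_mask, volume.data, -np.inf)
    hot_idx = np.unravel_index(int(np.argmax(masked)), volume.shape)
    radius_mm = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)  # 1 cm^3 sphere
    dist2 = np.zeros(volume.shape)
    for a in range(3):
        coord = (np.arange(volume.shape[a]) - hot_idx[a]) * volume.spacing[a]
        dist2 = dist2 + coord.reshape([-1 if i == a else 1 for i in range(3)]) ** 2
    in_sphere = dist2 <= radius_mm**2
    suv_peak = float(volume.data[in_sphere].mean())

    mtv = tumor_mask.sum() * volume.voxel_volume_cm3
    tlg = mtv * float(values.mean())
    return {"suv_max": suv_max, "suv_peak": suv_peak, "mtv_cm3": float(mtv), "tlg_g": float(tlg)}


def _surface_area_mm2(mask: np.ndarray, spacing) -> float:
    # Light anti-aliasing (0.5 voxel) before mesh extraction: a raw binary
    # marching-cubes mesh overestimates the area of smooth shapes by ~9%,
    # biasing sphericity low; heavier smoothing would distort small lesions.
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 3), sigma=0.5)
    if padded.max() <= 0.5:  # tiny mask smoothed below the iso level
        padded = np.pad(mask.astype(np.float64), 3)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def first_order_features(disc: DiscretizedVOI, spacing) -> dict[str, float]:
    """Histogram moments/entropy/energy of the discretized lesion plus shape.

    Skewness and kurtosis are the standardized third and fourth central
    moments of the grey-level histogram (kurtosis is not excess-corrected).
    Sphericity = (36 pi V^2)^(1/3) / A (1.0 for a perfect ball); compacity is
    its reciprocal, A / (36 pi V^2)^(1/3).
    """
    lv = disc.masked_levels.astype(np.float64)
    counts = np.bincount(disc.masked_levels, minlength=disc.n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    energy = float((nz**2).sum())

    m2 = float(lv.var())
    if lv.size < 2 or m2 == 0.0:
        skewness = kurtosis = float("nan")  # flagged missing: moments undefined
    else:
        centered = lv - lv.mean()
        skewness = float((centered**3).mean() / m2**1.5)
        kurtosis = float((centered**4).mean() / m2**2)

    voxvol = float(np.prod(spacing))
    volume_mm3 = disc.mask.sum() * voxvol
    area_mm2 = _surface_area_mm2(disc.mask, spacing)
    sphere_area = (36.0 * math.pi * volume_mm3**2) ** (1.0 / 3.0)
    sphericity = sphere_area / area_mm2
    compacity = area_mm2 / sphere_area
    return {
        "firstorder_skewness": skewness,
        "firstorder_kurtosis": kurtosis,
        "firstorder_entropy": entropy,
        "firstorder_energy": energy,
        "shape_sphericity": float(sphericity),
        "shape_compacity": float(compacity),
    }


def _shift_slices(shape, d: tuple[int, int, int]):
    """Slice tuples (sl_a, sl_b) such that arr[sl_b] is arr[sl_a] displaced by d."""
    sl_a, sl_b = [], []
    for step, n in zip(d, shape):
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step > 0:
            sl_a.append(slice(0, n - step))
            sl_b.append(slice(step, n))
        else:
            sl_a.append(slice(-step, n))
            sl_b.append(slice(0, n + step))
    return tuple(sl_a), tuple(sl_b)


def _shift_pairs(arr: np.ndarray, d: tuple[int, int, int]):
    """Aligned views (a, b) such that b is a displaced by d."""
    sl_a, sl_b = _shift_slices(arr.shape, d)
    return arr[sl_a], arr[sl_b]


def _glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int, merged: bool):
    """Symmetric co-occurrence counts; one merged matrix or 13 per-direction."""
    mats = []
    for d in DIRECTIONS_13:
        a, b = _shift_pairs(levels, d)
        ma, mb = _shift_pairs(mask, d)
        valid = ma & mb
        i = a[valid] - 1
        j = b[valid] - 1
        m = np.zeros((n_levels, n_levels))
        np.add.at(m, (i, j), 1.0)
        np.add.at(m, (j, i), 1.0)
        mats.append(m)
    if merged:
        return [sum(mats)]
    return mats


def _glcm_features(mat: np.ndarray) -> dict[str, float]:
    total = mat.sum()
    if total == 0:
        return {name: float("nan") for name in GLCM_NAMES}
    p = mat / total
    L = p.shape[0]
    i = np.arange(1, L + 1).reshape(-1, 1)
    j = np.arange(1, L + 1).reshape(1, -1)
    diff = np.abs(i - j)
    homogeneity = float((p / (1.0 + diff)).sum())
    energy = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i > 0 and var_j > 0:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum()) / math.sqrt(var_i * var_j))
    else:
        correlation = float("nan")  # single grey level: correlation undefined
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    dissimilarity = float((diff * p).sum())
    return {
        "glcm_homogeneity": homogeneity,
        "glcm_energy": energy,
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_entropy": entropy,
        "glcm_dissimilarity": dissimilarity,
    }


def _ngldm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level sum of |level - 26-neighbourhood mean| and voxel counts.

    Voxels with no in-mask neighbour are excluded (their neighbourhood mean
    is undefined).
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    m = mask.astype(np.float64)
    nb_sum = ndimage.correlate(levels * m, kernel, mode="constant")
    nb_cnt = ndimage.correlate(m, kernel, mode="constant")
    valid = mask & (nb_cnt > 0)
    with np.errstate(invalid="ignore"):
        nb_mean = np.where(nb_cnt > 0, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    absdiff = np.abs(levels - nb_mean)[valid]
    lev = levels[valid]
    s = np.zeros(n_levels)
    counts = np.zeros(n_levels)
    np.add.at(s, lev - 1, absdiff)
    np.add.at(counts, lev - 1, 1.0)
    return s, counts


def _ngldm_features(s: np.ndarray, counts: np.ndarray) -> dict[str, float]:
    n = counts.sum()
    if n == 0:
        return {name: float("nan") for name in NGLDM_NAMES}
    p = counts / n
    levels = np.arange(1, len(p) + 1, dtype=np.float64)
    occupied = p > 0
    ng = int(occupied.sum())
    ps_sum = float((p * s).sum())
    coarseness = 1.0 / ps_sum if ps_sum > 0 else float("nan")
    if ng > 1:
        pi = p[occupied].reshape(-1, 1)
        pj = p[occupied].reshape(1, -1)
        gi = levels[occupied].reshape(-1, 1)
        gj = levels[occupied].reshape(1, -1)
        contrast = float((pi * pj * (gi - gj) ** 2).sum() / (ng * (ng - 1)) * (s.sum() / n))
        denom = float(np.abs(gi * pi - gj * pj).sum())
        busyness = ps_sum / denom if denom > 0 else float("nan")
    else:
        contrast = busyness = float("nan")  # single grey level
    return {"ngldm_coarseness": coarseness, "ngldm_contrast": contrast, "ngldm_busyness": busyness}


def _glrlm_one_direction(levels: np.ndarray, mask: np.ndarray, n_levels: int, d) -> np.ndarray:
    """Run-length counts along direction d (runs of equal level inside the mask).

    Vectorized: run starts are voxels whose backward neighbour does not
    continue the run; all runs are then walked forward in lockstep.
    """
    sl_a, sl_b = _shift_slices(levels.shape, d)
    # continues[x] == True when voxel x+d extends the run through x
    continues = np.zeros(levels.shape, dtype=bool)
    continues[sl_a] = mask[sl_a] & mask[sl_b] & (levels[sl_a] == levels[sl_b])
    is_start = mask.copy()
    is_start[sl_b] &= ~continues[sl_a]

    coords = np.argwhere(is_start)
    g = levels[tuple(coords.T)]
    lengths = np.ones(len(coords), dtype=np.int64)
    pos = coords.copy()
    active = np.arange(len(coords))
    dvec = np.asarray(d)
    while active.size:
        p = pos[active]
        cont = continues[p[:, 0], p[:, 1], p[:, 2]]
        active = active[cont]
        lengths[active] += 1
        pos[active] += dvec

    max_run = int(lengths.max()) if lengths.size else 1
    mat = np.zeros((n_levels, max_run))
    np.add.at(mat, (g - 1, lengths - 1), 1.0)
    return mat


def _glzlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone-size counts: 26-connected components of constant grey level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_by_level: list[tuple[int, int]] = []
    max_zone = 1
    for g in np.unique(levels[mask]):
        labelled, n_comp = ndimage.label(mask & (levels == g), structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        for size in sizes:
            sizes_by_level.append((int(g), int(size)))
            max_zone = max(max_zone, int(size))
    mat = np.zeros((n_levels, max_zone))
    for g, size in sizes_by_level:
        mat[g - 1, size - 1] += 1
    return mat


def _rlm_features(mat: np.ndarray, n_voxels: int, prefix: str, names) -> dict[str, float]:
    """The 11 classical run/zone statistics of a length-distribution matrix."""
    nr = mat.sum()
    if nr == 0:
        return {name: float("nan") for name in names}
    L, maxlen = mat.shape
    i = np.arange(1, L + 1, dtype=np.float64).reshape(-1, 1)
    l = np.arange(1, maxlen + 1, dtype=np.float64).reshape(1, -1)
    vals = {
        f"{prefix}_s" + ("re" if prefix == "glrlm" else "ze"): float((mat / l**2).sum() / nr),
        f"{prefix}_l" + ("re" if prefix == "glrlm" else "ze"): float((mat * l**2).sum() / nr),
        f"{prefix}_lg" + ("re" if prefix == "glrlm" else "ze"): float((mat / i**2).sum() / nr),
        f"{prefix}_hg" + ("re" if prefix == "glrlm" else "ze"): float((mat * i**2).sum() / nr),
        (f"{prefix}_srlge" if prefix == "glrlm" else f"{prefix}_szlge"):
            float((mat / (i**2 * l**2)).sum() / nr),
        (f"{prefix}_srhge" if prefix == "glrlm" else f"{prefix}_szhge"):
            float((mat * i**2 / l**2).sum() / nr),
        (f"{prefix}_lrlge" if prefix == "glrlm" else f"{prefix}_lzlge"):
            float((mat * l**2 / i**2).sum() / nr),
        (f"{prefix}_lrhge" if prefix == "glrlm" else f"{prefix}_lzhge"):
            float((mat * i**2 * l**2).sum() / nr),
        f"{prefix}_glnu": float((mat.sum(axis=1) ** 2).sum() / nr),
        (f"{prefix}_rlnu" if prefix == "glrlm" else f"{prefix}_zlnu"):
            float((mat.sum(axis=0) ** 2).sum() / nr),
        (f"{prefix}_rp" if prefix == "glrlm" else f"{prefix}_zp"): float(nr / n_voxels),
    }
    assert set(vals) == set(names)
    return vals


def build_texture_matrices(disc: DiscretizedVOI, glcm_mode: str = "merged") -> TextureMatrices:
    """Build GLCM, NGLDM, GLRLM and GLZLM matrices of a discretized lesion."""
    if disc.mask.sum() < 2:
        raise ValueError("texture matrices need at least 2 lesion voxels")
    levels, mask = _crop_to_mask(disc.levels, disc.mask)
    levels = np.where(mask, levels, 0)
    glcm_mats = _glcm(levels, mask, disc.n_levels, merged=(glcm_mode == "merged"))
    glcm = sum(glcm_mats) if glcm_mode == "merged" else np.mean(glcm_mats, axis=0)
    s, counts = _ngldm(levels, mask, disc.n_levels)
    glrlm = tuple(
        _glrlm_one_direction(levels, mask, disc.n_levels, d) for d in DIRECTIONS_13
    )
    glzlm = _glzlm(levels, mask, disc.n_levels)
    return TextureMatrices(
        glcm=glcm,
        ngldm_s=s,
        ngldm_counts=counts,
        glrlm=glrlm,
        glzlm=glzlm,
        n_voxels=int(mask.sum()),
    )


def higher_order_features(mats: TextureMatrices) -> dict[str, float]:
    """The 31 higher-order texture features from pre-built matrices."""
    out: dict[str, float] = {}
    out.update(_glcm_features(mats.glcm))
    out.update(_ngldm_features(mats.ngldm_s, mats.ngldm_counts))
    per_dir = [_rlm_features(m, mats.n_voxels, "glrlm", GLRLM_NAMES) for m in mats.glrlm]
    for name in GLRLM_NAMES:
        out[name] = float(np.mean([f[name] for f in per_dir]))
    out.update(_rlm_features(mats.glzlm, mats.n_voxels, "glzlm", GLZLM_NAMES))
    assert len(out) == 31
    return out


def extract_all(
    volume: SUVVolume,
    tumor_mask: np.ndarray,
    levels: int = 64,
    glcm_mode: str = "merged",
) -> FeatureVector:
    """Extract all 41 imaging parameters of a segmented tumor.

    Lesions smaller than 64 voxels are rejected: texture statistics on such
    small supports are unstable, so they fall under the analysis exclusion
    floor.
    """
    tumor_mask = volume.check_mask(tumor_mask, "tumor mask")
    n = int(tumor_mask.sum())
    if n < MIN_TUMOR_VOXELS:
        raise ValueError(
            f"tumor has {n} voxels; radiomic analysis requires at least "
            f"{MIN_TUMOR_VOXELS} voxels"
        )
    values: dict[str, float] = {}
    values.update(conventional_params(volume, tumor_mask))
    disc = discretize(volume, tumor_mask, levels=levels)
    values.update(first_order_features(disc, volume.spacing))
    mats = build_texture_matrices(disc, glcm_mode=glcm_mode)
    values.update(higher_order_features(mats))
    return FeatureVector(values)
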