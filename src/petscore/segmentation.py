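"""Tumor delineation and bone-marrow / liver uptake measurement.

Tumor segmentation follows Nestle's adaptive threshold: within a manually
drawn VOI the tumor is the set of voxels at or above

    threshold = 0.3 * mean(SUV of voxels > 70% of the VOI maximum)
              + mean(SUV of background voxels)

Bone-marrow uptake (BM SUV) is the unweighted mean over up to six vertebral
VOIs of the mean SUV inside each vertebra's 75%-of-maximum isocontour; the
bone marrow-to-liver ratio (BLR) divides BM SUV by the plain mean SUV of a
liver VOI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import SUVVolume

__all__ = [
    "SegmentationResult",
    "MarrowMeasurement",
    "nestle_threshold",
    "default_background_shell",
    "isocontour_mean",
    "measure_bone_marrow",
]

HOT_FRACTION = 0.7  # "greater than 70% of maximum SUV" step of Nestle's formula


class EmptyTumorError(ValueError):
    """Raised when the adaptive threshold excludes every VOI voxel."""


@dataclass(frozen=True)
class SegmentationResult:
    """Outcome of Nestle adaptive-threshold delineation.

    Invariant: ``threshold == 0.3 * hot_mean + background_mean`` and every
    tumor-mask voxel lies inside the manual VOI with SUV >= threshold.
    """

    threshold: float
    tumor_mask: np.ndarray
    voxel_count: int
    hot_mean: float
    background_mean: float


@dataclass(frozen=True)
class MarrowMeasurement:
    """Per-vertebra 75%-isocontour means, their average (BM SUV), liver mean and BLR."""

    vertebra_suvs: tuple[float, ...]
    bm_suv: float
    liver_suv: float
    blr: float


def nestle_threshold(
    volume: SUVVolume,
    manual_voi: np.ndarray,
    background: np.ndarray,
    hot_fraction: float = HOT_FRACTION,
) -> SegmentationResult:
    """Delineate the tumor inside a manual VOI by Nestle's adaptive threshold.

    The hot-voxel set uses a strict ``>`` at ``hot_fraction`` of the VOI
    maximum (the maximum voxel itself always qualifies since max > 0.7*max
    for positive uptake); the final tumor mask keeps VOI voxels with SUV
    ``>=`` the threshold, so ties at the threshold are retained.

    Raises
    ------
    ValueError
        If the VOI is empty, the background is empty, or the two overlap.
    EmptyTumorError
        If the computed threshold exceeds the VOI maximum so no voxel survives.
    """
    manual_voi = volume.check_mask(manual_voi, "manual VOI")
    background = volume.check_mask(background, "background")
    if not manual_voi.any():
        raise ValueError("manual VOI is empty")
    if not background.any():
        raise ValueError("background mask is empty")
    if np.any(manual_voi & background):
        raise ValueError("background mask overlaps the manual VOI; they must be disjoint")

    voi_values = volume.data[manual_voi]
    vmax = float(voi_values.max())
    hot = voi_values[voi_values > hot_fraction * vmax]
    if hot.size == 0:  # only possible for an all-zero VOI
        raise EmptyTumorError("VOI has no uptake above the hot-voxel cutoff")
    hot_mean = float(hot.mean())
    background_mean = float(volume.data[background].mean())
    threshold = 0.3 * hot_mean + background_mean

    tumor_mask = manual_voi & (volume.data >= threshold)
    if not tumor_mask.any():
        raise EmptyTumorError(
            f"adaptive threshold {threshold:.4g} exceeds the VOI maximum {vmax:.4g}; "
            "no tumor voxel survives"
        )
    return SegmentationResult(
        threshold=threshold,
        tumor_mask=tumor_mask,
        voxel_count=int(tumor_mask.sum()),
        hot_mean=hot_mean,
        background_mean=background_mean,
    )


def default_background_shell(
    volume: SUVVolume,
    manual_voi: np.ndarray,
    thickness: int = 2,
    hot_fraction: float = HOT_FRACTION,
) -> np.ndarray:
    """Default background region: a shell of `thickness` voxels around the VOI.

    Voxels brighter than ``hot_fraction`` of the VOI maximum are excluded so
    spill-over from the lesion does not inflate the background estimate.
    Callers may always supply their own background mask instead.
    """
    manual_voi = volume.check_mask(manual_voi, "manual VOI")
    if not manual_voi.any():
        raise ValueError("manual VOI is empty")
    dilated = ndimage.binary_dilation(manual_voi, iterations=thickness)
    shell = dilated & ~manual_voi
    vmax = volume.data[manual_voi].max()
    shell &= volume.data <= hot_fraction * vmax
    if not shell.any():
        raise ValueError("background shell is empty (VOI touches the volume border everywhere?)")
    return shell


def isocontour_mean(volume: SUVVolume, voi: np.ndarray, fraction: float = 0.75) -> float:
    """Mean SUV over the VOI voxels at or above ``fraction`` of the VOI maximum.

    The maximum voxel is always included, so the result is well defined for
    any non-empty VOI and any fraction in (0, 1].
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"isocontour fraction must lie in (0, 1], got {fraction}")
    voi = volume.check_mask(voi, "VOI")
    if not voi.any():
        raise ValueError("VOI is empty")
    values = volume.data[voi]
    cutoff = fraction * values.max()
    return float(values[values >= cutoff].mean())


def measure_bone_marrow(
    volume: SUVVolume,
    vertebral_vois: list[np.ndarray],
    liver_voi: np.ndarray,
    fraction: float = 0.75,
) -> MarrowMeasurement:
    """Measure BM SUV, liver SUV and BLR from vertebral and liver VOIs.

    Accepts 1-6 vertebral VOIs (fewer than six models the exclusion of
    vertebrae with degenerative change). Each vertebra contributes the mean
    SUV within its 75% isocontour; the liver contributes its plain VOI mean.
    """
    if not 1 <= len(vertebral_vois) <= 6:
        raise ValueError(f"expected 1-6 vertebral VOIs, got {len(vertebral_vois)}")
    liver_voi = volume.check_mask(liver_voi, "liver VOI")
    if not liver_voi.any():
        raise ValueError("liver VOI is empty")

    vertebra_suvs = tuple(isocontour_mean(volume, voi, fraction) for voi in vertebral_vois)
    bm_suv = float(np.mean(vertebra_suvs))
    liver_suv = float(volume.data[liver_voi].mean())
    if liver_suv == 0.0:
        raise ValueError("liver mean SUV is zero; BLR is undefined")
    return MarrowMeasurement(
        vertebra_suvs=vertebra_suvs,
        bm_suv=bm_suv,
        liver_suv=liver_suv,
        blr=bm_suv / liver_suv,
    )
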