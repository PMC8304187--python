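"""Core imaging containers: SUV volumes and binary volumes of interest.

A PET volume is stored as a 3D array of standardized uptake values (SUV,
dimensionless) on a regular grid with physical voxel spacing in millimetres.
Masks (manually drawn VOIs, tumor delineations, vertebral and liver regions)
are plain boolean arrays on the same grid; every operation that pairs a mask
with a volume validates the shapes match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["SUVVolume", "load_volume", "save_volume", "load_mask", "save_mask"]


@dataclass(frozen=True)
class SUVVolume:
    """A 3D grid of SUV values with physical voxel spacing.

    Parameters
    ----------
    data
        3D float array of SUV values; all values must be >= 0.
    spacing
        Voxel edge lengths in mm, one per axis; all > 0.
    origin
        Physical coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {data.ndim} dimensions")
        if data.size == 0:
            raise ValueError("volume is empty")
        if np.any(data < 0):
            raise ValueError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of every voxel centre, as a meshgrid."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def check_mask(self, mask: np.ndarray, name: str = "mask") -> np.ndarray:
        """Validate a boolean mask against this volume's grid."""
        mask = np.asarray(mask)
        if mask.dtype != np.bool_:
            raise TypeError(f"{name} must be boolean, got dtype {mask.dtype}")
        if mask.shape != self.shape:
            raise ValueError(
                f"{name} shape {mask.shape} does not match volume shape {self.shape}"
            )
        return mask


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(volume: SUVVolume, path: str) -> None:
    """Write a volume to NIfTI (.nii or .nii.gz)."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing, volume.origin))
    nib.save(img, path)


def load_volume(path: str) -> SUVVolume:
    """Read a volume from NIfTI, recovering spacing from the affine."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, a])) for a in range(3))
    origin = tuple(float(x) for x in aff[:3, 3])
    return SUVVolume(data=data, spacing=spacing, origin=origin)


def save_mask(mask: np.ndarray, volume: SUVVolume, path: str) -> None:
    """Write a boolean mask aligned to `volume` as a uint8 NIfTI."""
    mask = volume.check_mask(mask)
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(volume.spacing, volume.origin))
    nib.save(img, path)


def load_mask(path: str) -> np.ndarray:
    img = nib.load(path)
    return np.asarray(img.dataobj) > 0
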