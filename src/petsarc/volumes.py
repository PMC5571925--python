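"""Core image containers: SUV volumes and lesion masks, with NIfTI I/O.

Volumes are axis-aligned 3-D grids. Array indices are voxel indices; physical
coordinates (mm) are obtained by multiplying the index by the per-axis voxel
spacing. Orientation/origin metadata beyond spacing is not interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

TIMEPOINTS = ("baseline", "post_cht")


@dataclass
class SuvVolume:
    """A 3-D PET volume in body-weight SUV units (g/mL).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative SUV values.
    spacing : tuple of 3 floats
        Voxel edge lengths in mm, one per axis.
    timepoint : str
        Either ``"baseline"`` or ``"post_cht"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D grid with >= 1 voxel per axis")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LesionMask:
    """Binary VOI aligned with a companion :class:`SuvVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def check_companion(self, vol: SuvVolume) -> None:
        """Raise if this mask is not aligned with ``vol``."""
        if self.values.shape != vol.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != volume shape {vol.values.shape}"
            )
        if not np.allclose(self.spacing, vol.spacing):
            raise ValueError(f"mask spacing {self.spacing} != volume spacing {vol.spacing}")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(vol: SuvVolume | LesionMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI; spacing goes into the affine/zooms."""
    data = vol.values.astype(np.uint8) if isinstance(vol, LesionMask) else vol.values
    img = nib.Nifti1Image(data, _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_suv_volume(path: str | Path, timepoint: str = "baseline") -> SuvVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing metadata {zooms}")
    return SuvVolume(np.asarray(img.dataobj, dtype=np.float64), tuple(zooms), timepoint)


def load_mask(path: str | Path) -> LesionMask:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing metadata {zooms}")
    return LesionMask(np.asarray(img.dataobj) > 0, tuple(zooms))
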