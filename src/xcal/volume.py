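"""Calibrated image volumes and binary masks on isotropic voxel grids.

The in-memory containers are deliberately thin: a numpy array plus the
isotropic voxel size in micrometres.  Grayscale volumes carry values in
volumetric bone mineral density units (mgHA/cm^3); a ``calibrated`` flag
records whether that calibration is meaningful.  File I/O goes through
SimpleITK (MetaImage ``.mha`` / NIfTI ``.nii.gz``), with the voxel size
stored in the image spacing (millimetres, the ITK convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = ["ImageVolume", "BinaryVolume", "read_volume", "write_volume"]


@dataclass
class ImageVolume:
    """3D grayscale volume calibrated in mgHA/cm^3 on an isotropic grid."""

    data: np.ndarray
    voxel_um: float
    calibrated: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume requires a 3D array")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm**3

    def total_mass(self) -> float:
        """Integral of the gray values over the volume (value x voxel volume)."""
        return float(self.data.sum() * self.voxel_volume_mm3)


@dataclass
class BinaryVolume:
    """3D boolean phase (bone, pore, mask ...) on an isotropic grid."""

    voxels: np.ndarray
    voxel_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("BinaryVolume requires a 3D array")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_fraction(self) -> float:
        return float(self.voxels.mean())


def write_volume(vol: ImageVolume | BinaryVolume, path: str | Path) -> None:
    """Write a volume as MetaImage/NIfTI; binary volumes are stored as uint8 {0,1}."""
    if isinstance(vol, BinaryVolume):
        arr = vol.voxels.astype(np.uint8)
    else:
        arr = vol.data.astype(np.float32)
    img = sitk.GetImageFromArray(arr)
    spacing_mm = vol.voxel_um / 1000.0
    img.SetSpacing((spacing_mm,) * 3)
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path, binary: bool = False) -> ImageVolume | BinaryVolume:
    """Read a volume written by :func:`write_volume`.

    The grid must be isotropic; anisotropic spacings are rejected.
    """
    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError(f"anisotropic voxel spacing {spacing} not supported")
    voxel_um = spacing[0] * 1000.0
    arr = sitk.GetArrayFromImage(img)
    if binary:
        return BinaryVolume(arr > 0, voxel_um)
    return ImageVolume(np.asarray(arr, dtype=np.float64), voxel_um)
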