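"""The CT volume container.

A :class:`CTVolume` is a 3-D scalar grid (Hounsfield units for images,
integer codes for label maps) with voxel spacing in mm and a world origin.
The grid-to-world map is the diagonal affine ``world = origin + index *
spacing`` in RAS+ orientation: index axis 0 points right, axis 1 anterior,
axis 2 superior.  Axis 2 is the longitudinal (axial-stack) axis everywhere
in this package; index 0 along it is the most inferior slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["CTVolume", "to_sitk", "from_sitk", "save_nifti", "load_nifti"]


@dataclass
class CTVolume:
    """3-D scalar grid with spacing (mm) and world origin (mm, RAS+)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume.data must be 3-D, got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"CTVolume.spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 grid-to-world affine (RAS+)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def is_label(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer) or self.data.dtype == bool

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (x, y, z) coordinates of every voxel centre, each shaped like data."""
        nx, ny, nz = self.shape
        x = self.origin[0] + np.arange(nx) * self.spacing[0]
        y = self.origin[1] + np.arange(ny) * self.spacing[1]
        z = self.origin[2] + np.arange(nz) * self.spacing[2]
        return np.meshgrid(x, y, z, indexing="ij")

    def like(self, data: np.ndarray) -> "CTVolume":
        """New volume on the same grid with different data."""
        return CTVolume(data, self.spacing, self.origin)

    def same_grid(self, other: "CTVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def to_sitk(vol: CTVolume) -> sitk.Image:
    """Convert to a SimpleITK image (which indexes arrays as z, y, x)."""
    arr = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def from_sitk(img: sitk.Image) -> CTVolume:
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return CTVolume(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def save_nifti(vol: CTVolume, path) -> None:
    """Write as NIfTI-1 (.nii or .nii.gz), RAS+ world coordinates in mm."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def load_nifti(path) -> CTVolume:
    img = nib.load(str(path))
    aff = img.affine
    off = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off, 0, atol=1e-6):
        raise ValueError(f"non-axis-aligned NIfTI affine in {path}")
    spacing = tuple(np.abs(np.diag(aff[:3, :3])))
    data = np.asanyarray(img.dataobj)
    return CTVolume(np.asarray(data), spacing, tuple(aff[:3, 3]))
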