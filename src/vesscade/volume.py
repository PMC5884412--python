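"""3D scalar volumes with physical spacing.

A :class:`Volume` is the carrier for angiographic images, feature maps and
binary masks: a 3D array plus voxel spacing and origin in millimetres.
Voxel centers sit at ``origin + index * spacing`` (0-based indices); all
geometry elsewhere in the package is expressed in these world coordinates.

I/O goes through nibabel (NIfTI) and SimpleITK (MetaImage, NRRD).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class VolumeError(ValueError):
    """Invalid volume data or metadata."""


@dataclass
class Volume:
    """3D scalar grid with anisotropic voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Voxel size per axis, mm. All components must be positive.
    origin
        World position of voxel (0, 0, 0), mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise VolumeError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_voxel(self, positions: np.ndarray) -> np.ndarray:
        """Map world (mm) positions to fractional voxel indices."""
        pos = np.asarray(positions, dtype=float)
        return (pos - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid geometry."""
        return Volume(data, self.spacing, self.origin)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin)


_NIFTI_EXTS = (".nii", ".nii.gz")
_ITK_EXTS = (".mha", ".mhd", ".nrrd")


def _splitext(path: str) -> str:
    lower = path.lower()
    if lower.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(lower)[1]


def load_volume(path: str) -> Volume:
    """Read a volume from NIfTI (.nii/.nii.gz), MetaImage (.mha/.mhd) or NRRD.

    Spacing and origin are taken from the file header; orientation matrices
    beyond axis scaling are not interpreted.
    """
    ext = _splitext(path)
    if ext in _NIFTI_EXTS:
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(x) for x in img.affine[:3, 3])
        return Volume(data, tuple(float(z) for z in zooms), origin)
    if ext in _ITK_EXTS:
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z).
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return Volume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    raise VolumeError(f"unsupported volume format: {path!r}")


def save_volume(volume: Volume, path: str) -> None:
    """Write a volume; format chosen from the file extension."""
    ext = _splitext(path)
    if ext in _NIFTI_EXTS:
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), path)
        return
    if ext in _ITK_EXTS:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, path)
        return
    raise VolumeError(f"unsupported volume format: {path!r}")
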