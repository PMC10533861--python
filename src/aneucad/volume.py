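"""3D scalar volumes with voxel-spacing metadata and NIfTI I/O.

A :class:`VoxelVolume` is the carrier of all image-domain computation.
World coordinates follow the voxel-center convention:
``world = origin + (index + 0.5) * spacing`` (all distances in mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "load_nifti", "save_nifti"]


@dataclass
class VoxelVolume:
    """A 3D intensity grid with per-axis voxel spacing.

    Parameters
    ----------
    intensities
        3D scalar array (any float or int dtype; converted to float64).
    spacing
        Voxel edge lengths in mm per axis, all > 0. May be anisotropic.
    origin
        World position (mm) of the corner of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.intensities.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinate (mm) of one or more voxel indices (voxel centers)."""
        return self.origin + (np.asarray(index, dtype=np.float64) + 0.5) * self.spacing

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel index for one or more world coordinates (mm)."""
        return (np.asarray(world, dtype=np.float64) - self.origin) / self.spacing - 0.5

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*grid_shape, 3)``."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


def load_nifti(path) -> VoxelVolume:
    """Read a NIfTI volume; spacing comes from the header zooms.

    Raises
    ------
    ValueError
        If the header carries no usable (positive) voxel spacing.
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: NIfTI header has no valid voxel spacing ({zooms})")
    data = np.asarray(img.dataobj, dtype=np.float64)
    origin = np.asarray(img.affine[:3, 3], dtype=np.float64)
    return VoxelVolume(data, np.asarray(zooms, dtype=np.float64), origin)


def save_nifti(volume: VoxelVolume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from the spacing."""
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))
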