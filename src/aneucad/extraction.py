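"""Front half of the detection pipeline: vessels, resampling, keypoints, patches.

The stages mirror a classical curvature-based candidate generator for
bright-blood angiography:

1. vessel extraction by global intensity thresholding (Otsu or percentile);
2. resampling of the anisotropic volume onto an isotropic grid
   (trilinear interpolation, world extent preserved);
3. keypoint detection from the principal curvatures (eigenvalues of the
   Gaussian-smoothed intensity Hessian): on a bright structure, three
   strongly negative curvatures indicate a blob-like bulge rather than a
   tube, whose smallest-magnitude curvature is ~0 along its axis;
4. extraction of a 5-slice stack of 24x24 in-plane patches around each
   keypoint for the downstream classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import VoxelVolume

__all__ = [
    "VesselMask",
    "KeyPoint",
    "PatchStack",
    "PATCH_SHAPE",
    "extract_vessels",
    "resample_isovoxel",
    "detect_keypoints",
    "extract_patch",
    "save_keypoint_csv",
]

logger = logging.getLogger(__name__)

#: slices x rows x cols of every classifier input patch
PATCH_SHAPE = (5, 24, 24)


@dataclass
class VesselMask:
    mask: np.ndarray
    source_shape: tuple[int, int, int]
    threshold: float | None = None  # intensity threshold used, None if degenerate

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.source_shape):
            raise ValueError(
                f"mask shape {self.mask.shape} != source shape {self.source_shape}"
            )


@dataclass
class KeyPoint:
    """A candidate seed proposed by principal-curvature analysis."""

    position: np.ndarray  # world mm
    voxel_index: tuple[int, int, int]  # index in the isovoxel grid
    curvature_value: float  # min |principal curvature| at the point
    score: float | None = None  # classifier output, set later

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass
class PatchStack:
    """A 5x24x24 intensity stack centered on a keypoint.

    ``pixel_spacing_mm`` records the in-plane pixel pitch of the source
    grid so geometric scorers can reason in millimetres.
    """

    values: np.ndarray
    source_keypoint: KeyPoint | None = None
    normalization_applied: bool = False
    pixel_spacing_mm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != PATCH_SHAPE:
            raise ValueError(f"patch must be {PATCH_SHAPE}, got {self.values.shape}")


def extract_vessels(
    volume: VoxelVolume, method: str = "otsu", q: float = 99.0
) -> VesselMask:
    """Segment bright vessels by global thresholding.

    Parameters
    ----------
    method
        ``"otsu"`` or ``"percentile"``; percentile keeps the top
        ``100 - q`` percent of voxels.

    A constant-intensity volume yields an empty mask with a warning: no
    threshold separates anything there.
    """
    intensities = volume.intensities
    if intensities.size == 0:
        raise ValueError("empty volume")
    lo, hi = float(intensities.min()), float(intensities.max())
    if lo == hi:
        logger.warning("constant-intensity volume: returning empty vessel mask")
        return VesselMask(np.zeros_like(intensities, dtype=bool), volume.shape, None)
    if method == "otsu":
        threshold = float(threshold_otsu(intensities))
    elif method == "percentile":
        if not 0.0 <= q <= 100.0:
            raise ValueError("percentile q must be in [0, 100]")
        threshold = float(np.percentile(intensities, q))
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    logger.info("vessel threshold (%s): %.4g", method, threshold)
    return VesselMask(intensities >= threshold, volume.shape, threshold)


def resample_isovoxel(volume: VoxelVolume, target_spacing: float | None = None) -> VoxelVolume:
    """Resample onto an isotropic grid by trilinear interpolation.

    ``target_spacing`` defaults to the smallest input spacing component
    (no information is discarded on any axis).  The world extent is
    preserved to within one voxel; an already-isotropic volume resampled
    to its own spacing is returned unchanged (same array, bit-identical).
    """
    if target_spacing is None:
        target_spacing = float(volume.spacing.min())
    if target_spacing <= 0:
        raise ValueError("target_spacing must be > 0")
    if volume.is_isotropic and np.isclose(volume.spacing[0], target_spacing):
        return volume
    extent = np.asarray(volume.shape) * volume.spacing
    new_shape = np.maximum(1, np.round(extent / target_spacing).astype(int))
    new_spacing = np.full(3, float(target_spacing))
    # fractional source indices of the new voxel centers (voxel-center convention)
    axes = [
        ((np.arange(new_shape[a]) + 0.5) * new_spacing[a]) / volume.spacing[a] - 0.5
        for a in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    resampled = ndimage.map_coordinates(
        volume.intensities, np.stack(coords), order=1, mode="nearest"
    )
    return VoxelVolume(resampled, new_spacing, volume.origin.copy())


def _hessian_eigenvalues(smoothed: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Per-voxel eigenvalues (ascending) of the finite-difference Hessian."""
    grads = np.gradient(smoothed, *spacing)
    hess = np.empty(smoothed.shape + (3, 3))
    for i in range(3):
        second = np.gradient(grads[i], *spacing)
        for j in range(3):
            hess[..., i, j] = second[j]
    # symmetrize: mixed finite differences are equal only up to rounding
    hess = 0.5 * (hess + np.swapaxes(hess, -1, -2))
    return np.linalg.eigvalsh(hess)


def detect_keypoints(
    volume: VoxelVolume,
    mask: VesselMask,
    smoothing_scale_mm: float = 1.0,
    curvature_cutoff: float = 1e-4,
) -> list[KeyPoint]:
    """Detect blob-like keypoints from the principal curvatures.

    The volume is Gaussian-smoothed at ``smoothing_scale_mm``, intensities
    are rescaled to [0, 1] so the curvature magnitudes (units 1/mm^2 of
    normalized intensity) are comparable across acquisitions, and the
    Hessian eigenvalues are computed per masked voxel.  A voxel is
    blob-like when all three principal curvatures are negative (bright
    compact structure) and the smallest magnitude, min|lambda|, exceeds
    ``curvature_cutoff``; keypoints are the local maxima of min|lambda|
    within a 3x3x3 neighborhood (non-maximum suppression).

    Requires an isotropic volume (run :func:`resample_isovoxel` first).
    """
    if not volume.is_isotropic:
        raise ValueError("detect_keypoints requires an isotropic volume")
    if mask.mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    if curvature_cutoff < 0:
        raise ValueError("curvature_cutoff must be >= 0")
    if not mask.mask.any():
        return []

    sigma_vox = smoothing_scale_mm / volume.spacing
    smoothed = ndimage.gaussian_filter(volume.intensities, sigma_vox)
    span = smoothed.max() - smoothed.min()
    if span > 0:
        smoothed = (smoothed - smoothed.min()) / span
    eigs = _hessian_eigenvalues(smoothed, volume.spacing)
    all_negative = np.all(eigs < 0, axis=-1)
    # eigenvalues ascend, so for all-negative spectra min|lambda| = |largest|
    blobness = np.where(all_negative, -eigs[..., 2], 0.0)
    candidate = mask.mask & all_negative & (blobness > curvature_cutoff)
    local_max = blobness == ndimage.maximum_filter(blobness, size=3, mode="constant")
    candidate &= local_max

    keypoints = [
        KeyPoint(
            position=volume.voxel_to_world(np.array(idx)),
            voxel_index=tuple(int(i) for i in idx),
            curvature_value=float(blobness[idx]),
        )
        for idx in zip(*np.nonzero(candidate))
    ]
    logger.info("detected %d keypoints", len(keypoints))
    return keypoints


def extract_patch(
    volume: VoxelVolume, keypoint: KeyPoint, normalize: bool = True
) -> PatchStack:
    """Cut the 5x24x24 stack around a keypoint: 5 consecutive slices along
    the third (axial) axis, each a 24x24 in-plane window centered on the
    keypoint.  Out-of-grid voxels are zero-filled; with ``normalize`` the
    intensities are min-max scaled to [0, 1] over the patch (a zero-range
    patch maps to all zeros).
    """
    ix, iy, iz = keypoint.voxel_index
    shape = volume.shape
    if not (0 <= ix < shape[0] and 0 <= iy < shape[1] and 0 <= iz < shape[2]):
        raise ValueError(f"keypoint voxel index {keypoint.voxel_index} outside grid {shape}")
    n_slices, rows, cols = PATCH_SHAPE
    patch = np.zeros(PATCH_SHAPE)
    x0, y0, z0 = ix - rows // 2, iy - cols // 2, iz - n_slices // 2
    for s in range(n_slices):
        z = z0 + s
        if not 0 <= z < shape[2]:
            continue
        xs0, xs1 = max(x0, 0), min(x0 + rows, shape[0])
        ys0, ys1 = max(y0, 0), min(y0 + cols, shape[1])
        if xs0 >= xs1 or ys0 >= ys1:
            continue
        patch[s, xs0 - x0 : xs1 - x0, ys0 - y0 : ys1 - y0] = volume.intensities[
            xs0:xs1, ys0:ys1, z
        ]
    if normalize:
        span = patch.max() - patch.min()
        patch = (patch - patch.min()) / span if span > 0 else np.zeros(PATCH_SHAPE)
    return PatchStack(
        patch,
        keypoint,
        normalization_applied=normalize,
        pixel_spacing_mm=float(volume.spacing[0]),
    )


def save_keypoint_csv(keypoints: list[KeyPoint], path, case_id: str = "case") -> None:
    pd.DataFrame(
        {
            "case_id": case_id,
            "x_mm": [k.position[0] for k in keypoints],
            "y_mm": [k.position[1] for k in keypoints],
            "z_mm": [k.position[2] for k in keypoints],
            "curvature_value": [k.curvature_value for k in keypoints],
            "score": [k.score if k.score is not None else np.nan for k in keypoints],
        }
    ).to_csv(path, index=False)
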