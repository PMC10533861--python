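"""End-to-end candidate detection: volume in, scored candidates out.

Chains the pipeline stages in their canonical order — vessel thresholding,
isovoxel resampling, principal-curvature keypoint detection, patch
extraction, patch scoring, score-cutoff filtering, clustering, candidate
finalization and optional top-k limiting — logging per-stage object counts
(the quantities that cutoff tuning acts on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .extraction import (
    VesselMask,
    detect_keypoints,
    extract_patch,
    extract_vessels,
    resample_isovoxel,
)
from .postprocess import (
    PostprocessConfig,
    ScoredCandidate,
    cluster_keypoints,
    filter_by_threshold,
    finalize_candidates,
    limit_candidates,
)
from .volume import VoxelVolume

__all__ = ["DetectionConfig", "detect_candidates"]

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """All knobs of one detection run."""

    threshold_method: str = "otsu"
    percentile_q: float = 99.0
    target_spacing_mm: float | None = None  # None -> min input spacing
    smoothing_scale_mm: float = 1.0
    curvature_cutoff: float = 1e-4
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)


def detect_candidates(
    volume: VoxelVolume, scorer, config: DetectionConfig | None = None
) -> list[ScoredCandidate]:
    """Run the full detection pipeline on one volume.

    ``scorer`` is any object with ``score_patches`` (the trained network
    or the analytic rule scorer).  Returns the final candidates sorted by
    descending score.
    """
    config = config or DetectionConfig()

    mask = extract_vessels(volume, config.threshold_method, config.percentile_q)
    iso = resample_isovoxel(volume, config.target_spacing_mm)
    if iso is volume:
        iso_mask = mask
    elif mask.threshold is None:
        iso_mask = VesselMask(np.zeros(iso.shape, dtype=bool), iso.shape, None)
    else:
        # same global threshold re-applied on the resampled intensities
        iso_mask = VesselMask(iso.intensities >= mask.threshold, iso.shape, mask.threshold)
    logger.info("vessel mask: %d voxels", int(iso_mask.mask.sum()))

    keypoints = detect_keypoints(
        iso, iso_mask, config.smoothing_scale_mm, config.curvature_cutoff
    )
    if not keypoints:
        return []
    patches = [extract_patch(iso, kp) for kp in keypoints]
    scores = scorer.score_patches(patches)
    for kp, score in zip(keypoints, scores):
        kp.score = float(score)

    survivors = filter_by_threshold(keypoints, config.postprocess.cutoff_threshold)
    clusters = cluster_keypoints(survivors, config.postprocess.linkage_radius_mm)
    candidates = finalize_candidates(clusters, config.postprocess.cluster_score)
    logger.info(
        "keypoints %d -> survivors at cutoff %.2f: %d -> clusters %d",
        len(keypoints), config.postprocess.cutoff_threshold, len(survivors), len(clusters),
    )
    if config.postprocess.max_candidates is not None:
        candidates = limit_candidates(candidates, config.postprocess.max_candidates)
    return candidates
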