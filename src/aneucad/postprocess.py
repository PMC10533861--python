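"""Back half of the pipeline: score filtering, clustering, final candidates.

Keypoints below the score cutoff are removed first; the survivors are then
grouped by single-linkage clustering (connected components of the graph
joining points within a linkage radius), each cluster is reduced to its
center of gravity (unweighted mean of member positions), and the candidate
list may finally be truncated to the top k by score.  Because filtering
precedes clustering, raising the cutoff both suppresses outputs and
removes noisy keypoints from surviving clusters, sharpening their
centroids — cutoff tuning (the studied 0.5 -> 0.8 change) is therefore
not a pure sensitivity/precision trade-off.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .extraction import KeyPoint

__all__ = [
    "PostprocessConfig",
    "Cluster",
    "ScoredCandidate",
    "filter_by_threshold",
    "cluster_keypoints",
    "finalize_candidates",
    "limit_candidates",
    "save_candidates_csv",
]


@dataclass
class PostprocessConfig:
    """Operating point of the postprocessing stage.

    ``cutoff_threshold`` is the studied tuning parameter (0.5 before,
    0.8 after tuning); ``linkage_radius_mm`` the single-linkage merge
    distance; ``max_candidates`` an optional per-case output cap.
    ``cluster_score`` selects how a cluster inherits its members' scores
    (``"max"`` default, ``"mean"`` alternative).
    """

    cutoff_threshold: float = 0.5
    linkage_radius_mm: float = 5.0
    max_candidates: int | None = None
    cluster_score: str = "max"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff_threshold <= 1.0:
            raise ValueError("cutoff_threshold must be in [0, 1]")
        if self.linkage_radius_mm <= 0:
            raise ValueError("linkage_radius_mm must be > 0")
        if self.max_candidates is not None and self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1 when set")
        if self.cluster_score not in ("max", "mean"):
            raise ValueError("cluster_score must be 'max' or 'mean'")

    @classmethod
    def from_json(cls, path) -> "PostprocessConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Cluster:
    members: list[KeyPoint]
    centroid: np.ndarray

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster needs at least one member")
        self.centroid = np.asarray(self.centroid, dtype=np.float64)


@dataclass
class ScoredCandidate:
    """A final detector output: cluster center of gravity plus score."""

    position: np.ndarray
    score: float
    n_members: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def filter_by_threshold(keypoints: list[KeyPoint], cutoff: float) -> list[KeyPoint]:
    """Keep exactly the keypoints with score >= cutoff, preserving order.

    The comparison is inclusive so a cutoff of 1.0 still passes perfectly
    confident scores.  Unscored keypoints are an error, not a silent drop.
    """
    for kp in keypoints:
        if kp.score is None:
            raise ValueError("filter_by_threshold requires every keypoint to be scored")
    return [kp for kp in keypoints if kp.score >= cutoff]


def cluster_keypoints(keypoints: list[KeyPoint], linkage_radius_mm: float) -> list[Cluster]:
    """Single-linkage clustering: connected components of the graph joining
    keypoints at Euclidean distance <= ``linkage_radius_mm``.

    Every input point lands in exactly one cluster; the partition and the
    centroids are invariant to input order.
    """
    if linkage_radius_mm <= 0:
        raise ValueError("linkage_radius_mm must be > 0")
    if not keypoints:
        return []
    positions = np.array([kp.position for kp in keypoints])
    pairs = cKDTree(positions).query_pairs(linkage_radius_mm, output_type="ndarray")
    n = len(keypoints)
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for comp in range(n_comp):
        members = [keypoints[i] for i in np.nonzero(labels == comp)[0]]
        centroid = np.mean([kp.position for kp in members], axis=0)
        clusters.append(Cluster(members, centroid))
    return clusters


def finalize_candidates(
    clusters: list[Cluster], cluster_score: str = "max"
) -> list[ScoredCandidate]:
    """One candidate per cluster: center of gravity of the member keypoints,
    score aggregated over members (max by default), sorted by descending
    score."""
    candidates = []
    for cluster in clusters:
        scores = [kp.score for kp in cluster.members]
        if any(s is None for s in scores):
            raise ValueError("finalize_candidates requires scored keypoints")
        score = max(scores) if cluster_score == "max" else float(np.mean(scores))
        candidates.append(ScoredCandidate(cluster.centroid, float(score), len(cluster.members)))
    candidates.sort(key=_candidate_sort_key)
    return candidates


def _candidate_sort_key(cand: ScoredCandidate):
    # descending score, ties to larger clusters, then lexicographic position
    return (-cand.score, -cand.n_members, tuple(cand.position))


def limit_candidates(candidates: list[ScoredCandidate], k: int) -> list[ScoredCandidate]:
    """Top-k candidates by score (deterministic tie-breaks: larger cluster
    first, then lexicographically smaller position).  ``limit(k)`` is always
    a prefix of ``limit(k + 1)``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(candidates, key=_candidate_sort_key)[:k]


def save_candidates_csv(candidates: list[ScoredCandidate], path, case_id: str = "case") -> None:
    pd.DataFrame(
        {
            "case_id": case_id,
            "rank": range(len(candidates)),
            "x_mm": [c.position[0] for c in candidates],
            "y_mm": [c.position[1] for c in candidates],
            "z_mm": [c.position[2] for c in candidates],
            "score": [c.score for c in candidates],
            "n_members": [c.n_members for c in candidates],
        }
    ).to_csv(path, index=False)
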