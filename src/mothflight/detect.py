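"""Per-frame object detection: chained-proximity clustering and size gating.

Residual points (after background subtraction) are grouped by
single-linkage Euclidean clustering: two points belong to the same
object if they are connected by a chain of points with consecutive
gaps of at most 1 cm.  Clusters whose point count falls outside the
moth-plausible window [20, 900] are discarded.  Both bounds and the
link distance are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io import FrameCloud

__all__ = [
    "DetectedObject",
    "cluster_points",
    "filter_by_size",
    "detect_objects",
    "bounding_box_volume",
]

DEFAULT_LINK_DIST_M = 0.01
DEFAULT_MIN_PTS = 20
DEFAULT_MAX_PTS = 900


def bounding_box_volume(points: np.ndarray) -> float:
    """Axis-aligned outline-box volume (m^3) of a point set.

    Zero whenever all points are coplanar along a coordinate axis —
    the signature of a degenerate stereo reconstruction.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] == 0:
        return 0.0
    extents = pts.max(axis=0) - pts.min(axis=0)
    return float(np.prod(extents))


@dataclass(frozen=True)
class DetectedObject:
    """One clustered point group in one frame."""

    frame_index: int
    point_indices: np.ndarray  # indices into the frame's point array
    points: np.ndarray         # (point_count, 3) member coordinates
    centroid: np.ndarray       # arithmetic mean of member points
    point_count: int

    @property
    def obv_m3(self) -> float:
        return bounding_box_volume(self.points)

    @property
    def distance_from_camera_m(self) -> float:
        return float(np.linalg.norm(self.centroid))


def cluster_points(
    frame: FrameCloud | np.ndarray,
    link_dist_m: float = DEFAULT_LINK_DIST_M,
) -> list[np.ndarray]:
    """Connected components of the <= ``link_dist_m`` proximity graph.

    Equivalent to brute-force single linkage on the pairwise distance
    matrix but computed with a KD-tree.  Groups are returned with
    member indices sorted, ordered by their smallest member index, so
    the partition is invariant under permutation of the input points.
    """
    points = frame.points if isinstance(frame, FrameCloud) else np.asarray(frame, dtype=np.float64)
    n = points.shape[0]
    if n == 0:
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=link_dist_m, output_type="ndarray")
    if pairs.size:
        graph = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    boundaries = np.flatnonzero(np.diff(sorted_labels)) + 1
    groups = [np.sort(g) for g in np.split(order, boundaries)]
    groups.sort(key=lambda g: g[0])
    return groups


def filter_by_size(
    frame: FrameCloud,
    groups: list[np.ndarray],
    min_pts: int = DEFAULT_MIN_PTS,
    max_pts: int = DEFAULT_MAX_PTS,
) -> list[DetectedObject]:
    """Keep groups with min_pts <= size <= max_pts as DetectedObjects.

    Clusters outside the window are too small or too large to be a
    moth at the camera's working distances.
    """
    objects = []
    for group in groups:
        size = len(group)
        if size < min_pts or size > max_pts:
            continue
        member = frame.points[group]
        objects.append(
            DetectedObject(
                frame_index=frame.frame_index,
                point_indices=group,
                points=member,
                centroid=member.mean(axis=0),
                point_count=size,
            )
        )
    return objects


def detect_objects(
    frame: FrameCloud,
    link_dist_m: float = DEFAULT_LINK_DIST_M,
    min_pts: int = DEFAULT_MIN_PTS,
    max_pts: int = DEFAULT_MAX_PTS,
) -> list[DetectedObject]:
    """Cluster one background-filtered frame and apply the size gate."""
    return filter_by_size(frame, cluster_points(frame, link_dist_m), min_pts, max_pts)
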