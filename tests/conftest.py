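import numpy as np
import pytest
from hypothesis import settings

from mothflight.detect import DetectedObject
from mothflight.track import Trajectory

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def brute_force_single_linkage(points: np.ndarray, link_dist: float) -> list[frozenset]:
    """O(N^2) union-find oracle for single-linkage connected components."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= link_dist:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def traj_from_centroids(
    centroids: np.ndarray,
    extents=(0.04, 0.04, 0.04),
    start_frame: int = 0,
    point_count: int = 50,
    trajectory_id: int = 0,
    frame_indices=None,
) -> Trajectory:
    """Build a Trajectory whose detections are symmetric corner boxes.

    ``extents`` may be a single (ex, ey, ez) triple or one per frame; the
    detection's bounding box then has exactly those extents and its point
    mean equals the requested centroid.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    n = len(centroids)
    ext = np.asarray(extents, dtype=np.float64)
    if ext.ndim == 1:
        ext = np.tile(ext, (n, 1))
    corners = np.array(
        [[dx, dy, dz] for dx in (-0.5, 0.5) for dy in (-0.5, 0.5) for dz in (-0.5, 0.5)]
    )
    if frame_indices is None:
        frame_indices = range(start_frame, start_frame + n)
    detections = []
    for i, fi in zip(range(n), frame_indices):
        pts = centroids[i][None, :] + corners * ext[i][None, :]
        detections.append(
            DetectedObject(
                frame_index=int(fi),
                point_indices=np.arange(len(pts)),
                points=pts,
                centroid=centroids[i].copy(),
                point_count=point_count,
            )
        )
    return Trajectory(trajectory_id=trajectory_id, detections=detections)


@pytest.fixture(scope="session")
def small_scene():
    """One-moth scene with noise, shared across tests that only read it."""
    from mothflight import SceneConfig, simulate_scene

    config = SceneConfig(n_frames=80, n_moths=1, n_noise_events=4, rng_seed=11)
    sequence, truth = simulate_scene(config)
    return config, sequence, truth
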