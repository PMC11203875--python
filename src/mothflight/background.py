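"""Static-background modelling on a cubic voxel grid.

The first four frames of a recording are assumed to contain the static
scene (arena net, walls, fixtures).  Space is discretised into cubic
voxels (default 5 cm sides); a voxel occupied in at least two of the
four training frames is designated background, and every point falling
in a background voxel is removed from subsequent frames.

Voxel keys are ``floor(coord / voxel_size)`` per axis with the grid
anchored at the camera origin; cells are half-open, so a point exactly
on a boundary belongs to the higher-index voxel, and negative
coordinates use the true floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FrameCloud

__all__ = ["VoxelBackground", "voxel_keys", "fit_background", "remove_background"]

DEFAULT_VOXEL_SIZE_M = 0.05
N_TRAINING_FRAMES = 4
MIN_OCCUPANCY_FRAMES = 2


def voxel_keys(points: np.ndarray, voxel_size_m: float) -> np.ndarray:
    """Integer (N, 3) voxel keys for an (N, 3) point array."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    return np.floor(pts / voxel_size_m).astype(np.int64)


@dataclass
class VoxelBackground:
    voxel_size_m: float = DEFAULT_VOXEL_SIZE_M
    occupied_keys: set[tuple[int, int, int]] = field(default_factory=set)
    n_training_frames: int = N_TRAINING_FRAMES
    min_occupancy_frames: int = MIN_OCCUPANCY_FRAMES

    def __contains__(self, key: tuple[int, int, int]) -> bool:
        return tuple(key) in self.occupied_keys


def fit_background(
    frames: list[FrameCloud],
    voxel_size_m: float = DEFAULT_VOXEL_SIZE_M,
    n_training_frames: int = N_TRAINING_FRAMES,
    min_occupancy_frames: int = MIN_OCCUPANCY_FRAMES,
) -> VoxelBackground:
    """Designate as background every voxel occupied in >= 2 of the first 4 frames.

    ``frames`` must contain exactly ``n_training_frames`` clouds.  A
    voxel counts as occupied in a frame if the frame has at least one
    point in it; multiplicity within a frame does not matter.
    """
    if len(frames) != n_training_frames:
        raise ValueError(
            f"background fit needs exactly {n_training_frames} frames, got {len(frames)}"
        )
    counts: dict[tuple[int, int, int], int] = {}
    for frame in frames:
        keys = voxel_keys(frame.points, voxel_size_m)
        for key in set(map(tuple, keys)):
            counts[key] = counts.get(key, 0) + 1
    occupied = {k for k, c in counts.items() if c >= min_occupancy_frames}
    return VoxelBackground(
        voxel_size_m=voxel_size_m,
        occupied_keys=occupied,
        n_training_frames=n_training_frames,
        min_occupancy_frames=min_occupancy_frames,
    )


def remove_background(frame: FrameCloud, bg: VoxelBackground) -> FrameCloud:
    """Drop every point whose voxel key is in the background set.

    Point order is preserved; the operation is idempotent.
    """
    if frame.n_points == 0 or not bg.occupied_keys:
        return frame
    keys = voxel_keys(frame.points, bg.voxel_size_m)
    occupied = np.array(sorted(bg.occupied_keys), dtype=np.int64)
    void = np.dtype((np.void, keys.dtype.itemsize * 3))
    keys_v = np.ascontiguousarray(keys).view(void).ravel()
    occ_v = np.ascontiguousarray(occupied).view(void).ravel()
    mask = ~np.isin(keys_v, occ_v)
    return FrameCloud(
        frame_index=frame.frame_index,
        points=frame.points[mask],
        timestamp_s=frame.timestamp_s,
    )
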