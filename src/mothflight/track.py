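"""Frame-to-frame linking of detected objects into trajectories.

Each object is linked to its nearest-centroid successor in the next
frame if that distance is within a 9 cm gate; conflicts for a shared
successor are resolved greedily by ascending distance (ties by lower
object index).  A trajectory terminates the first frame it finds no
successor — a single missed frame ends it, since discontinuity is
itself a noise signature.  Trajectories shorter than 10 frames are
discarded as noise.

For laser aiming the tracker also extrapolates a constant-velocity
prediction a configurable number of frames ahead (two frames = 36 ms
at the 55 fps update rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import DetectedObject

__all__ = [
    "Trajectory",
    "link_frames",
    "build_trajectories",
    "predict_position",
    "update_interval_ms",
    "prediction_lead_ms",
]

DEFAULT_GATE_M = 0.09
DEFAULT_MIN_LENGTH_FRAMES = 10
DEFAULT_STEPS_AHEAD = 2


@dataclass
class Trajectory:
    """Time-ordered detections of one putative real object."""

    trajectory_id: int
    detections: list[DetectedObject] = field(default_factory=list)
    label: str = "unlabeled"  # unlabeled | moth | noise

    @property
    def centroids(self) -> np.ndarray:
        return np.array([d.centroid for d in self.detections], dtype=np.float64)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections], dtype=np.int64)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame_index

    def __len__(self) -> int:
        return len(self.detections)


def link_frames(
    objects_t: list[DetectedObject],
    objects_t1: list[DetectedObject],
    gate_m: float = DEFAULT_GATE_M,
) -> list[tuple[int, int]]:
    """Match frame-t objects to their nearest frame-(t+1) centroids.

    Each frame-t object proposes only its single nearest successor; a
    proposal is accepted if the distance is within the gate and the
    successor is still free, processing proposals in ascending distance
    (then ascending frame-t index).  Losers stay unmatched.
    """
    if not objects_t or not objects_t1:
        return []
    c_t = np.array([o.centroid for o in objects_t])
    c_t1 = np.array([o.centroid for o in objects_t1])
    dists = np.linalg.norm(c_t[:, None, :] - c_t1[None, :, :], axis=2)
    nearest = dists.argmin(axis=1)
    proposals = sorted(
        (dists[i, nearest[i]], i, int(nearest[i]))
        for i in range(len(objects_t))
        if dists[i, nearest[i]] <= gate_m
    )
    taken: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in proposals:
        if j in taken:
            continue
        taken.add(j)
        matches.append((i, j))
    matches.sort()
    return matches


def build_trajectories(
    detections_per_frame: list[list[DetectedObject]],
    gate_m: float = DEFAULT_GATE_M,
    min_length_frames: int = DEFAULT_MIN_LENGTH_FRAMES,
) -> list[Trajectory]:
    """Assemble gap-free trajectories from chronological detection lists.

    Unmatched detections seed new trajectories; trajectories with fewer
    than ``min_length_frames`` detections are dropped (short time-series
    length marks noise).  Output is sorted by start frame then id.
    """
    next_id = 0
    active: list[Trajectory] = []
    finished: list[Trajectory] = []
    for t in range(len(detections_per_frame)):
        objs = detections_per_frame[t]
        if t == 0:
            for obj in objs:
                active.append(Trajectory(trajectory_id=next_id, detections=[obj]))
                next_id += 1
            continue
        prev_tails = [traj.detections[-1] for traj in active]
        matches = dict(link_frames(prev_tails, objs, gate_m))
        still_active: list[Trajectory] = []
        matched_j: set[int] = set()
        for i, traj in enumerate(active):
            j = matches.get(i)
            if j is None:
                finished.append(traj)
            else:
                traj.detections.append(objs[j])
                matched_j.add(j)
                still_active.append(traj)
        for j, obj in enumerate(objs):
            if j not in matched_j:
                still_active.append(Trajectory(trajectory_id=next_id, detections=[obj]))
                next_id += 1
        active = still_active
    finished.extend(active)
    kept = [t for t in finished if len(t) >= min_length_frames]
    kept.sort(key=lambda t: (t.start_frame, t.trajectory_id))
    return kept


def predict_position(trajectory: Trajectory, steps_ahead: int = DEFAULT_STEPS_AHEAD) -> np.ndarray:
    """Constant-velocity extrapolation from the last two centroids."""
    if len(trajectory) < 2:
        raise ValueError("prediction needs at least 2 detections")
    c = trajectory.centroids
    return c[-1] + steps_ahead * (c[-1] - c[-2])


def update_interval_ms(frame_rate_fps: float = 55.0) -> float:
    """Time per stereo update in milliseconds (1000 / fps)."""
    return 1000.0 / frame_rate_fps


def prediction_lead_ms(steps_ahead: int = DEFAULT_STEPS_AHEAD, frame_rate_fps: float = 55.0) -> float:
    """Lead time of an n-step-ahead prediction in milliseconds."""
    return steps_ahead * update_interval_ms(frame_rate_fps)
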