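"""Per-frame flight kinematics and the post-tracking noise filters.

For each tracked frame the module computes speed (backward difference
of centroids times the frame rate), turning angle (between consecutive
displacement vectors, backward-looking), the outline-box volume (OBV,
axis-aligned bounding box of the frame's member points), point density
and distance from the camera.  Undefined entries (speed at the first
frame, turning angle at the first two, density when OBV = 0) are NaN,
never zero-filled.

Three filters refine the candidate set:

1. OBV = 0 removal — a volume-less outline box means every point of the
   frame lies on one plane, a stereo artifact seen near the camera's
   minimum effective range (~0.9 m).
2. Turning-angle removal — any step turning strictly more than 110°
   marks reciprocating noise (real flight stays below; noise occupies
   110° < θ <= 180°).
3. Iterative interquartile-range screen — Tukey fences on pooled OBV
   and turning angle flag extreme trajectories; flagged trajectories
   confirmed by an automated noise proxy (limited net displacement or a
   frame discontinuity) are removed, and the fences are recomputed
   until a fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import turning_angles_deg
from .track import Trajectory

__all__ = [
    "FrameKinematics",
    "TrajectoryStats",
    "compute_kinematics",
    "trajectory_table",
    "filter_zero_obv",
    "filter_turning_angle",
    "iqr_outlier_screen",
    "noise_proxy",
    "summarize",
]

DEFAULT_MAX_ANGLE_DEG = 110.0
DEFAULT_FENCE_K = 1.5
OBV_ZERO_TOL_M3 = 1e-12
NOISE_NET_DISPLACEMENT_M = 0.05


@dataclass(frozen=True)
class FrameKinematics:
    frame_index: int
    centroid: np.ndarray
    speed_mps: float            # NaN at the trajectory's first frame
    turning_angle_deg: float    # NaN at the first two frames
    obv_m3: float
    point_count: int
    density_pts_per_m3: float   # NaN when obv == 0
    distance_from_camera_m: float


def compute_kinematics(trajectory: Trajectory, frame_rate_fps: float) -> list[FrameKinematics]:
    """Per-frame kinematics for one trajectory (length >= 2 required)."""
    n = len(trajectory.detections)
    if n < 2:
        raise ValueError("kinematics need a trajectory of length >= 2")
    c = trajectory.centroids
    speeds = np.full(n, np.nan)
    speeds[1:] = np.linalg.norm(np.diff(c, axis=0), axis=1) * frame_rate_fps
    angles = np.full(n, np.nan)
    if n >= 3:
        angles[2:] = turning_angles_deg(c)
    out = []
    for i, det in enumerate(trajectory.detections):
        obv = det.obv_m3
        density = det.point_count / obv if obv > 0 else math.nan
        out.append(
            FrameKinematics(
                frame_index=det.frame_index,
                centroid=det.centroid,
                speed_mps=float(speeds[i]),
                turning_angle_deg=float(angles[i]),
                obv_m3=obv,
                point_count=det.point_count,
                density_pts_per_m3=density,
                distance_from_camera_m=det.distance_from_camera_m,
            )
        )
    return out


def trajectory_table(trajectory: Trajectory, frame_rate_fps: float) -> pd.DataFrame:
    """Kinematics as a tidy per-frame DataFrame (the trajectory-CSV schema)."""
    from .io import TRAJECTORY_CSV_COLUMNS

    if len(trajectory.detections) >= 2:
        kin = compute_kinematics(trajectory, frame_rate_fps)
        rows = [
            {
                "frame_index": k.frame_index,
                "centroid_x": k.centroid[0],
                "centroid_y": k.centroid[1],
                "centroid_z": k.centroid[2],
                "point_count": k.point_count,
                "obv_m3": k.obv_m3,
                "speed_mps": k.speed_mps,
                "turning_angle_deg": k.turning_angle_deg,
                "distance_from_camera_m": k.distance_from_camera_m,
                "density_pts_per_m3": k.density_pts_per_m3,
            }
            for k in kin
        ]
    else:
        det = trajectory.detections[0]
        obv = det.obv_m3
        rows = [
            {
                "frame_index": det.frame_index,
                "centroid_x": det.centroid[0],
                "centroid_y": det.centroid[1],
                "centroid_z": det.centroid[2],
                "point_count": det.point_count,
                "obv_m3": obv,
                "speed_mps": math.nan,
                "turning_angle_deg": math.nan,
                "distance_from_camera_m": det.distance_from_camera_m,
                "density_pts_per_m3": det.point_count / obv if obv > 0 else math.nan,
            }
        ]
    return pd.DataFrame(rows, columns=TRAJECTORY_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# Filters


def _traj_obvs(traj: Trajectory) -> np.ndarray:
    return np.array([d.obv_m3 for d in traj.detections])


def filter_zero_obv(
    trajectories: list[Trajectory],
    tol_m3: float = OBV_ZERO_TOL_M3,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Remove trajectories containing any frame with zero outline-box volume."""
    kept, removed = [], []
    for traj in trajectories:
        (removed if bool((_traj_obvs(traj) <= tol_m3).any()) else kept).append(traj)
    return kept, removed


def filter_turning_angle(
    trajectories: list[Trajectory],
    max_angle_deg: float = DEFAULT_MAX_ANGLE_DEG,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Remove trajectories with any turning angle strictly above the cutoff.

    A trajectory whose sharpest turn is exactly the cutoff is kept
    (noise occupies the open interval above it).
    """
    kept, removed = [], []
    for traj in trajectories:
        angles = turning_angles_deg(traj.centroids)
        (removed if bool((angles > max_angle_deg).any()) else kept).append(traj)
    return kept, removed


def noise_proxy(traj: Trajectory, net_displacement_m: float = NOISE_NET_DISPLACEMENT_M) -> bool:
    """Automated stand-in for visual trajectory inspection.

    True (noise) if the trajectory barely moves over its lifetime
    (net displacement below 5 cm) or its frame indices are
    discontinuous — the two visual signatures of residual noise.
    """
    c = traj.centroids
    net = float(np.linalg.norm(c[-1] - c[0]))
    gaps = np.diff(traj.frame_indices)
    return net < net_displacement_m or bool((gaps != 1).any())


def _metric_frame_flags(traj: Trajectory, metric: str, lo: float, hi: float,
                        two_sided: bool) -> np.ndarray:
    """Boolean per-frame outlier flags for one trajectory and metric."""
    n = len(traj.detections)
    flags = np.zeros(n, dtype=bool)
    if metric == "obv":
        v = _traj_obvs(traj)
        flags |= v > hi
        if two_sided:
            flags |= v < lo
    else:  # turning_angle: angle at frame t uses frames t-2, t-1, t
        v = turning_angles_deg(traj.centroids)
        if v.size:
            flags[2:] = v > hi
    return flags


def iqr_outlier_screen(
    trajectories: list[Trajectory],
    metrics: tuple[str, ...] = ("obv", "turning_angle"),
    fence_k: float = DEFAULT_FENCE_K,
    max_iterations: int = 20,
    confirm=noise_proxy,
    mode: str = "trajectory",
    min_length_frames: int = 2,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Iterative Tukey-fence outlier screen over pooled frame metrics.

    Per iteration and metric, quartiles are pooled over all frames of
    the currently kept trajectories; a trajectory is flagged if any of
    its frames exceeds Q3 + k·IQR (or, for OBV, also falls below
    Q1 − k·IQR).  Flagged trajectories confirmed by ``confirm`` — an
    automated stand-in for frame-by-frame visual inspection — are
    removed and the fences recomputed, until no removal or
    ``max_iterations``.  Fewer than 4 trajectories: quartiles are not
    meaningful, so the screen is a no-op.

    ``mode="trajectory"`` (default) removes the whole confirmed
    trajectory; ``mode="trim"`` instead trims contiguous flagged frames
    off the trajectory's ends (noise often brackets a genuine flight
    segment), removing it only if fewer than ``min_length_frames``
    frames survive.
    """
    if mode not in ("trajectory", "trim"):
        raise ValueError(f"unknown IQR mode {mode!r}")
    if len(trajectories) < 4:
        return list(trajectories), []
    kept = list(trajectories)
    removed: list[Trajectory] = []
    for _ in range(max_iterations):
        fences: dict[str, tuple[float, float, bool]] = {}
        for metric in metrics:
            if metric == "obv":
                pooled = [_traj_obvs(t) for t in kept]
                two_sided = True
            elif metric == "turning_angle":
                pooled = [turning_angles_deg(t.centroids) for t in kept]
                two_sided = False
            else:
                raise ValueError(f"unknown IQR metric {metric!r}")
            flat = np.concatenate([v for v in pooled if v.size]) if pooled else np.zeros(0)
            if flat.size < 4:
                continue
            q1, q3 = np.percentile(flat, [25, 75])
            iqr = q3 - q1
            fences[metric] = (q1 - fence_k * iqr, q3 + fence_k * iqr, two_sided)
        flagged: dict[int, np.ndarray] = {}
        for idx, t in enumerate(kept):
            frame_flags = np.zeros(len(t.detections), dtype=bool)
            for metric, (lo, hi, two_sided) in fences.items():
                frame_flags |= _metric_frame_flags(t, metric, lo, hi, two_sided)
            if frame_flags.any():
                flagged[idx] = frame_flags
        changed = False
        next_kept: list[Trajectory] = []
        for idx, t in enumerate(kept):
            if idx not in flagged or not confirm(t):
                next_kept.append(t)
                continue
            if mode == "trajectory":
                removed.append(t)
                changed = True
                continue
            flags = flagged[idx]
            lo_i = int(np.argmax(~flags)) if not flags.all() else len(flags)
            hi_i = len(flags) - int(np.argmax(~flags[::-1])) if not flags.all() else 0
            if hi_i - lo_i >= min_length_frames:
                trimmed = Trajectory(
                    trajectory_id=t.trajectory_id,
                    detections=t.detections[lo_i:hi_i],
                    label=t.label,
                )
                next_kept.append(trimmed)
                changed = changed or (lo_i > 0 or hi_i < len(flags))
            else:
                removed.append(t)
                changed = True
        kept = next_kept
        if not changed:
            break
    return kept, removed


# ---------------------------------------------------------------------------
# Descriptive statistics


@dataclass
class TrajectoryStats:
    """Pooled and per-trajectory descriptive statistics of flight kinematics."""

    n_trajectories: int
    n_speed_samples: int
    speed_mean_mps: float
    speed_sd_mps: float
    speed_median_mps: float
    speed_q1_mps: float
    speed_q3_mps: float
    turning_mean_deg: float
    turning_sd_deg: float
    turning_median_deg: float
    turning_q1_deg: float
    turning_q3_deg: float
    per_trajectory_mean_speed_mps: list[float] = field(default_factory=list)

    @property
    def mean_of_trajectory_means_mps(self) -> float:
        return float(np.mean(self.per_trajectory_mean_speed_mps))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_trajectories", "n_speed_samples",
            "speed_mean_mps", "speed_sd_mps", "speed_median_mps",
            "speed_q1_mps", "speed_q3_mps",
            "turning_mean_deg", "turning_sd_deg", "turning_median_deg",
            "turning_q1_deg", "turning_q3_deg",
        )}
        d["per_trajectory_mean_speed_mps"] = list(self.per_trajectory_mean_speed_mps)
        d["mean_of_trajectory_means_mps"] = self.mean_of_trajectory_means_mps
        return d


def summarize(trajectories: list[Trajectory], frame_rate_fps: float) -> TrajectoryStats:
    """Pooled per-frame speed/turning statistics across kept trajectories.

    Speeds pool every defined per-step speed of every trajectory;
    per-trajectory mean speeds are also reported since "mean flight
    speed" can be read either way.
    """
    if not trajectories:
        raise ValueError("no trajectories to summarize")
    speeds, angles, per_traj_means = [], [], []
    for traj in trajectories:
        c = traj.centroids
        s = np.linalg.norm(np.diff(c, axis=0), axis=1) * frame_rate_fps
        speeds.append(s)
        angles.append(turning_angles_deg(c))
        per_traj_means.append(float(s.mean()) if s.size else math.nan)
    speeds = np.concatenate(speeds)
    angles = np.concatenate(angles) if any(a.size for a in angles) else np.zeros(0)

    def q(a, p):
        return float(np.percentile(a, p)) if a.size else math.nan

    return TrajectoryStats(
        n_trajectories=len(trajectories),
        n_speed_samples=int(speeds.size),
        speed_mean_mps=float(speeds.mean()) if speeds.size else math.nan,
        speed_sd_mps=float(speeds.std(ddof=1)) if speeds.size > 1 else math.nan,
        speed_median_mps=q(speeds, 50),
        speed_q1_mps=q(speeds, 25),
        speed_q3_mps=q(speeds, 75),
        turning_mean_deg=float(angles.mean()) if angles.size else math.nan,
        turning_sd_deg=float(angles.std(ddof=1)) if angles.size > 1 else math.nan,
        turning_median_deg=q(angles, 50),
        turning_q1_deg=q(angles, 25),
        turning_q3_deg=q(angles, 75),
        per_trajectory_mean_speed_mps=per_traj_means,
    )
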