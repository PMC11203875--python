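"""Histogram/boxplot and 3D-path exports for human review."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .classify import turning_angles_deg
from .track import Trajectory

__all__ = ["plot_speed_turning_panels", "plot_trajectory_paths"]


def _pooled(trajectories: list[Trajectory], frame_rate_fps: float):
    speeds, angles = [], []
    for traj in trajectories:
        c = traj.centroids
        speeds.append(np.linalg.norm(np.diff(c, axis=0), axis=1) * frame_rate_fps)
        angles.append(turning_angles_deg(c))
    return (
        np.concatenate(speeds) if speeds else np.zeros(0),
        np.concatenate(angles) if angles else np.zeros(0),
    )


def plot_speed_turning_panels(
    categories: dict[str, list[Trajectory]],
    frame_rate_fps: float,
    path: str | Path,
) -> Path:
    """Histogram + boxplot of speed and turning angle per data category.

    ``categories`` maps a label (e.g. entire / moth / noisy) to its
    trajectories; one row per category, speed left, turning angle right.
    """
    n = max(len(categories), 1)
    fig, axes = plt.subplots(n, 2, figsize=(9, 3 * n), squeeze=False)
    for row, (name, trajs) in enumerate(categories.items()):
        speeds, angles = _pooled(trajs, frame_rate_fps)
        for col, (vals, label, unit) in enumerate(
            [(speeds, "speed", "m/s"), (angles, "turning angle", "deg")]
        ):
            ax = axes[row][col]
            if vals.size:
                ax.hist(vals, bins=30, color="0.6")
                ax.axvline(vals.mean(), linestyle=":", color="k")
                box = ax.inset_axes([0, 1.02, 1, 0.15])
                box.boxplot(vals, orientation="horizontal", widths=0.6)
                box.set_axis_off()
            ax.set_xlabel(f"{label} ({unit})")
            ax.set_ylabel(f"{name}\ncount")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_trajectory_paths(trajectories: list[Trajectory], path: str | Path) -> Path:
    """3D centroid paths of trajectories, one colour each."""
    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    for traj in trajectories:
        c = traj.centroids
        ax.plot(c[:, 0], c[:, 2], c[:, 1], label=f"traj {traj.trajectory_id}")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("z, depth (m)")
    ax.set_zlabel("y (m)")
    if trajectories and len(trajectories) <= 10:
        ax.legend(fontsize=7)
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
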