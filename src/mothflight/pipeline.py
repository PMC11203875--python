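"""End-to-end pipeline: voxel background removal, clustering, size gate,
tracking, SVM classification, OBV / turning-angle / IQR denoising, stats.

Every stage reports kept + removed counts and the run asserts their
conservation, so a report documents exactly where candidate data went.
Identical configuration and input give a byte-identical JSON report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import background, detect, kinematics, track
from .classify import LinearModel, extract_features, train_classifier
from .classify import classify as classify_trajectory
from .io import FrameSequence, read_frame_sequence, write_trajectory_csv
from .simulate import make_training_paths

__all__ = ["PipelineConfig", "train_default_classifier", "process_sequence", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage thresholds, with the recording system's defaults."""

    voxel_size_m: float = 0.05
    n_training_frames: int = 4
    min_occupancy_frames: int = 2
    link_dist_m: float = 0.01
    min_pts: int = 20
    max_pts: int = 900
    gate_m: float = 0.09
    min_length_frames: int = 10
    window_frames: int = 10
    max_angle_deg: float = 110.0
    fence_k: float = 1.5
    frame_rate_fps: float = 55.0
    steps_ahead: int = 2
    tracking_start_frame: int = 4
    classifier_mode: str = "final"  # final | sliding
    iqr_mode: str = "trajectory"    # trajectory | trim
    model_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def train_default_classifier(
    seed: int = 0,
    n_per_class: int = 200,
    window_frames: int = 10,
) -> LinearModel:
    """Fit the moth/noise model on synthetic labelled trajectories.

    No trained weights ship with the camera system, so a model is
    fitted on centroid paths drawn from the simulator's flight and
    transient-noise models.
    """
    paths, labels = make_training_paths(n_per_class, seed)
    feats = [extract_features(p, window_frames) for p in paths]
    return train_classifier(feats, labels, seed=seed)


def process_sequence(
    sequence: FrameSequence,
    config: PipelineConfig = PipelineConfig(),
    model: LinearModel | None = None,
) -> tuple[list[track.Trajectory], dict]:
    """Run all pipeline stages on an in-memory frame sequence.

    Returns the surviving moth trajectories and the run report.
    """
    if model is None:
        if config.model_path:
            model = LinearModel.from_json(config.model_path)
        else:
            model = train_default_classifier(seed=config.seed, window_frames=config.window_frames)

    report: dict = {"config": config.to_dict(), "steps": {}}

    # step 1: static background from the first frames
    bg = background.fit_background(
        list(sequence)[: config.n_training_frames],
        voxel_size_m=config.voxel_size_m,
        n_training_frames=config.n_training_frames,
        min_occupancy_frames=config.min_occupancy_frames,
    )
    filtered = [background.remove_background(f, bg) for f in sequence]
    points_in = int(sum(f.n_points for f in sequence))
    points_kept = int(sum(f.n_points for f in filtered))
    report["steps"]["background"] = {
        "n_background_voxels": len(bg.occupied_keys),
        "points_in": points_in,
        "points_removed": points_in - points_kept,
        "points_kept": points_kept,
    }
    assert points_kept + (points_in - points_kept) == points_in

    # step 2: clustering + size gate, from the configured start frame
    start = min(config.tracking_start_frame, len(filtered))
    detections: list[list[detect.DetectedObject]] = []
    n_clusters = 0
    for frame in filtered[start:]:
        groups = detect.cluster_points(frame, config.link_dist_m)
        n_clusters += len(groups)
        detections.append(detect.filter_by_size(frame, groups, config.min_pts, config.max_pts))
    n_objects = sum(len(d) for d in detections)
    report["steps"]["detection"] = {
        "start_frame": start,
        "n_clusters": n_clusters,
        "n_objects_kept": n_objects,
        "n_clusters_removed": n_clusters - n_objects,
    }

    # step 3: frame-to-frame linking, short-trajectory removal
    trajectories = track.build_trajectories(detections, config.gate_m, config.min_length_frames)
    detections_tracked = sum(len(t) for t in trajectories)
    report["steps"]["tracking"] = {
        "detections_in": n_objects,
        "n_trajectories": len(trajectories),
        "detections_in_kept_trajectories": detections_tracked,
        "detections_in_short_trajectories": n_objects - detections_tracked,
    }

    # step 4: linear SVM moth/noise classification
    kept, removed = [], []
    for traj in trajectories:
        label = classify_trajectory(traj, model, config.window_frames, mode=config.classifier_mode)
        traj.label = label
        (kept if label == "moth" else removed).append(traj)
    report["steps"]["classifier"] = {"in": len(trajectories), "kept": len(kept), "removed": len(removed)}
    assert len(kept) + len(removed) == len(trajectories)

    # step 5: zero outline-box-volume (coplanar stereo artifacts)
    kept2, removed_obv = kinematics.filter_zero_obv(kept)
    report["steps"]["obv_filter"] = {"in": len(kept), "kept": len(kept2), "removed": len(removed_obv)}
    assert len(kept2) + len(removed_obv) == len(kept)

    # step 6: turning-angle cutoff (reciprocating noise)
    kept3, removed_angle = kinematics.filter_turning_angle(kept2, config.max_angle_deg)
    report["steps"]["turning_filter"] = {"in": len(kept2), "kept": len(kept3), "removed": len(removed_angle)}
    assert len(kept3) + len(removed_angle) == len(kept2)

    # step 7: iterative IQR outlier screen with the automated noise proxy
    kept4, removed_iqr = kinematics.iqr_outlier_screen(
        kept3, fence_k=config.fence_k, mode=config.iqr_mode
    )
    report["steps"]["iqr_screen"] = {"in": len(kept3), "kept": len(kept4), "removed": len(removed_iqr)}

    final: dict = {"n_trajectories": len(kept4)}
    if kept4:
        stats = kinematics.summarize(kept4, config.frame_rate_fps)
        final["stats"] = stats.to_dict()
    report["final"] = final
    return kept4, report


def run_pipeline(
    config: PipelineConfig,
    input_dir: str | Path,
    out_dir: str | Path | None = None,
    model: LinearModel | None = None,
) -> dict:
    """Read a PLY frame directory, run all stages, optionally write outputs.

    Outputs: one trajectory CSV per surviving trajectory plus
    ``report.json`` (sorted keys, so identical runs are byte-identical).
    """
    sequence = read_frame_sequence(input_dir, frame_rate=config.frame_rate_fps)
    kept, report = process_sequence(sequence, config, model=model)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for traj in kept:
            write_trajectory_csv(
                traj, out / f"trajectory_{traj.trajectory_id:04d}.csv", config.frame_rate_fps
            )
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
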