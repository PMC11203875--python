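"""Synthetic recording-arena scenes with per-point ground truth.

The original recordings are not public, so this module generates
labelled stand-ins with the same statistical signatures, in the same
geometry: a 1.8 m x 1.8 m x 3.5 m netted arena observed from one short
side by a 55 fps stereo camera with a 47.2° x 36.3° field of view.

Three populations of points are rendered per frame:

* **Background** — fixed points on the arena walls (the net is a
  static, slightly rough surface), identical across frames up to a
  sub-millimetre jitter much smaller than the background voxel size.
* **Moths** — each moth flies a C1-smooth path: heading follows a
  damped random walk with the per-frame turn capped (default 40°),
  per-step speeds drawn around a configurable mean; the body renders
  as an isotropic Gaussian blob of 60–400 points.
* **Noise events** — the two artifact morphologies seen in real
  recordings: *transient blobs* that live 1–60 frames with near-zero
  net displacement and reciprocating direction (turning angles
  concentrated in 110°–180°), and *coplanar artifacts* whose points
  all share one exact depth plane near the camera's ~0.9 m minimum
  effective range, so their outline-box volume is exactly zero.

Points outside the camera frustum are dropped; everything is
deterministic given the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .detect import cluster_points
from .io import FrameCloud, FrameSequence

__all__ = [
    "SceneConfig",
    "NoiseEvent",
    "SceneTruth",
    "simulate_scene",
    "render_moth_blob",
    "sample_moth_path",
    "sample_noise_path",
    "make_training_paths",
]

LABEL_BACKGROUND = 0  # moths are 1..n_moths, noise event k is -(k+1)


@dataclass(frozen=True)
class SceneConfig:
    """Scene parameters; defaults mirror the recording conditions."""

    arena_extent: tuple[float, float, float] = (1.8, 1.8, 3.5)  # width, height, depth
    frame_rate_fps: float = 55.0
    n_frames: int = 120
    n_moths: int = 1
    moth_speed_mean_mps: float = 1.8
    moth_speed_sd_mps: float = 0.3
    moth_points_range: tuple[int, int] = (60, 400)
    moth_spread_m: float = 0.02
    background_density: float = 1200.0  # points per m^2 of wall
    background_jitter_m: float = 0.0005
    n_noise_events: int = 4
    noise_points_range: tuple[int, int] = (30, 300)
    near_range_m: float = 0.9
    fov_h_deg: float = 47.2
    fov_v_deg: float = 36.3
    z_near_m: float = 0.3
    max_turn_deg: float = 40.0
    heading_sigma: float = 0.12
    separate_moths: bool = False
    moth_entry_frame: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.arena_extent):
            raise ValueError("arena extents must be positive")
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4 (the background model trains on 4 frames)")
        if self.moth_points_range[0] > self.moth_points_range[1]:
            raise ValueError("moth_points_range low must be <= high")
        if self.n_moths < 0 or self.n_noise_events < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class NoiseEvent:
    event_id: int
    kind: Literal["transient_blob", "coplanar_artifact"]
    start_frame: int
    positions: np.ndarray  # (lifetime, 3) per-frame blob centres

    @property
    def lifetime(self) -> int:
        return self.positions.shape[0]

    @property
    def frames(self) -> range:
        return range(self.start_frame, self.start_frame + self.lifetime)


@dataclass
class SceneTruth:
    """Per-point labels and generating paths for one simulated scene.

    ``labels[t][i]`` labels point i of frame t: 0 background, moth id
    (1-based) for moths, -(event_id + 1) for noise events.

    ``moth_paths`` cover every frame; frames before the configured entry
    frame describe the flight before the moth reaches the field of view
    and are not rendered (no points carry that moth's label there).
    """

    labels: list[np.ndarray]
    moth_paths: dict[int, np.ndarray]      # moth_id -> (n_frames, 3)
    noise_events: dict[int, NoiseEvent] = field(default_factory=dict)

    def moth_speeds(self, moth_id: int, frame_rate_fps: float) -> np.ndarray:
        """Ground-truth per-step speeds (m/s) of one moth."""
        path = self.moth_paths[moth_id]
        return np.linalg.norm(np.diff(path, axis=0), axis=1) * frame_rate_fps

    def all_moth_speeds(self, frame_rate_fps: float) -> np.ndarray:
        if not self.moth_paths:
            return np.zeros(0)
        return np.concatenate(
            [self.moth_speeds(m, frame_rate_fps) for m in sorted(self.moth_paths)]
        )


# ---------------------------------------------------------------------------
# Geometry helpers


def _frustum_mask(points: np.ndarray, config: SceneConfig, margin: float = 0.0) -> np.ndarray:
    tan_h = math.tan(math.radians(config.fov_h_deg / 2.0))
    tan_v = math.tan(math.radians(config.fov_v_deg / 2.0))
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    return (
        (z >= config.z_near_m + margin)
        & (np.abs(x) <= z * tan_h - margin)
        & (np.abs(y) <= z * tan_v - margin)
    )


def _rotate_towards(u: np.ndarray, v: np.ndarray, max_angle_rad: float) -> np.ndarray:
    """Rotate unit vector u towards unit vector v by at most max_angle."""
    cosang = float(np.clip(u @ v, -1.0, 1.0))
    angle = math.acos(cosang)
    if angle <= max_angle_rad:
        return v
    axis = np.cross(u, v)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:  # (anti)parallel: pick any perpendicular axis
        helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, helper)
        norm = np.linalg.norm(axis)
    axis = axis / norm
    s, c = math.sin(max_angle_rad), math.cos(max_angle_rad)
    return c * u + s * np.cross(axis, u) + (1 - c) * (axis @ u) * axis


def _default_flight_box(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """A box inside both the arena and the camera frustum for moth flight."""
    lo = np.array([-0.55, -0.40, 1.4])
    hi = np.array([0.55, 0.40, 3.3])
    half_w = config.arena_extent[0] / 2.0
    half_h = config.arena_extent[1] / 2.0
    depth = config.arena_extent[2]
    lo = np.maximum(lo, [-half_w + 0.1, -half_h + 0.1, 0.1])
    hi = np.minimum(hi, [half_w - 0.1, half_h - 0.1, depth - 0.2])
    return lo, hi


def _moth_boxes(config: SceneConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    lo, hi = _default_flight_box(config)
    n = config.n_moths
    if not config.separate_moths or n <= 1:
        return [(lo, hi)] * n
    # disjoint sub-boxes on an (x, z) grid with a 0.25 m buffer between cells,
    # guaranteeing pairwise moth separation well above the tracking gate
    buffer = 0.25
    gx = 1 if n <= 2 else 2
    gz = math.ceil(n / gx)
    spans = []
    for axis, cells in ((0, gx), (2, gz)):
        span = hi[axis] - lo[axis]
        cell = (span - (cells - 1) * buffer) / cells
        if cell < 0.25:
            raise ValueError(f"cannot fit {n} separated moths in the flight volume")
        spans.append([(lo[axis] + i * (cell + buffer), lo[axis] + i * (cell + buffer) + cell)
                      for i in range(cells)])
    boxes = []
    for k in range(n):
        ix, iz = k % gx, k // gx
        blo, bhi = lo.copy(), hi.copy()
        blo[0], bhi[0] = spans[0][ix]
        blo[2], bhi[2] = spans[1][iz]
        boxes.append((blo, bhi))
    return boxes


# ---------------------------------------------------------------------------
# Path models


def sample_moth_path(
    n_frames: int,
    rng: np.random.Generator,
    box: tuple[np.ndarray, np.ndarray],
    speed_mean_mps: float = 1.8,
    speed_sd_mps: float = 0.3,
    dt_s: float = 1.0 / 55.0,
    max_turn_deg: float = 40.0,
    heading_sigma: float = 0.12,
    margin_m: float = 0.3,
) -> np.ndarray:
    """Smooth free-flight path: damped-random-walk heading, capped turn rate.

    The heading receives an isotropic Gaussian perturbation each frame
    (typical turn ~8–10° at the default sigma) and is steered back
    toward the box centre when within ``margin_m`` of a wall, with the
    per-frame turn never exceeding ``max_turn_deg`` — so the turning-
    angle filter's 110° cutoff is never tripped by a real flight.
    """
    lo, hi = box
    max_turn = math.radians(max_turn_deg)
    centre = (lo + hi) / 2.0
    pos = rng.uniform(lo + margin_m / 2, hi - margin_m / 2)
    heading = rng.normal(size=3)
    heading /= np.linalg.norm(heading)
    path = np.empty((n_frames, 3))
    path[0] = pos
    for t in range(1, n_frames):
        proposal = heading + heading_sigma * rng.normal(size=3)
        proposal /= np.linalg.norm(proposal)
        # steering pressure grows as the moth nears any box face
        gap = np.minimum(pos - lo, hi - pos)
        pressure = float(np.clip((margin_m - gap.min()) / margin_m, 0.0, 1.0))
        if pressure > 0:
            inward = centre - pos
            inward /= np.linalg.norm(inward)
            desired = proposal + 2.0 * pressure * inward
            desired /= np.linalg.norm(desired)
        else:
            desired = proposal
        heading = _rotate_towards(heading, desired, max_turn)
        speed = max(rng.normal(speed_mean_mps, speed_sd_mps), 0.1 * speed_mean_mps)
        pos = pos + heading * speed * dt_s
        pos = np.clip(pos, lo, hi)  # safety net; steering keeps flight inside
        path[t] = pos
    return path


def sample_noise_path(
    n_frames: int,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
    amplitude_m: float | None = None,
    jitter_m: float = 0.003,
) -> np.ndarray:
    """Reciprocating low-movement path typical of transient stereo noise.

    The blob oscillates around a fixed base along one axis, so
    consecutive displacements nearly reverse (turning angles
    concentrated in 110°–180°) and the net displacement over any
    lifetime stays below 5 cm.
    """
    if base is None:
        base = np.array([0.0, 0.0, 1.5])
    if amplitude_m is None:
        amplitude_m = rng.uniform(0.01, 0.03)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    signs = np.where(np.arange(n_frames) % 2 == 0, 0.5, -0.5)
    path = base[None, :] + signs[:, None] * amplitude_m * axis[None, :]
    path = path + jitter_m * rng.normal(size=(n_frames, 3))
    return path


def make_training_paths(
    n_per_class: int,
    seed: int,
    n_frames: int = 14,
    config: SceneConfig | None = None,
    centroid_noise_m: float = 0.0015,
) -> tuple[list[np.ndarray], list[str]]:
    """Labelled centroid paths for classifier training/evaluation.

    Moth paths follow the flight model (plus centroid measurement noise
    at the level induced by blob averaging); noise paths follow the
    reciprocating transient model.  Returns (paths, labels).
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    box = _default_flight_box(cfg)
    paths: list[np.ndarray] = []
    labels: list[str] = []
    for _ in range(n_per_class):
        p = sample_moth_path(
            n_frames, rng, box,
            speed_mean_mps=cfg.moth_speed_mean_mps,
            speed_sd_mps=cfg.moth_speed_sd_mps,
            dt_s=1.0 / cfg.frame_rate_fps,
            max_turn_deg=cfg.max_turn_deg,
            heading_sigma=cfg.heading_sigma,
        )
        paths.append(p + centroid_noise_m * rng.normal(size=p.shape))
        labels.append("moth")
    lo, hi = box
    for _ in range(n_per_class):
        base = rng.uniform(lo, hi)
        paths.append(sample_noise_path(n_frames, rng, base=base))
        labels.append("noise")
    return paths, labels


# ---------------------------------------------------------------------------
# Rendering


def render_moth_blob(
    centroid: np.ndarray,
    n_points: int,
    spread_m: float,
    rng: np.random.Generator,
    link_dist_m: float = 0.01,
) -> np.ndarray:
    """Isotropic Gaussian point blob guaranteed single-linkage connected.

    Offsets are drawn from an isotropic Gaussian with SD ``spread_m``;
    if the resulting set splits at the clustering link distance the
    offsets are contracted toward the centroid until one cluster
    remains (always terminates), so the detector sees one object.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    centroid = np.asarray(centroid, dtype=np.float64)
    offsets = rng.normal(scale=spread_m, size=(n_points, 3))
    while n_points > 1 and len(cluster_points(offsets, link_dist_m)) > 1:
        offsets *= 0.8
    return centroid[None, :] + offsets


def _render_coplanar_blob(
    centre: np.ndarray,
    n_points: int,
    spread_m: float,
    rng: np.random.Generator,
    link_dist_m: float = 0.01,
) -> np.ndarray:
    """Blob with all points at exactly one depth (zero-thickness artifact)."""
    pts = render_moth_blob(centre, n_points, spread_m, rng, link_dist_m)
    pts[:, 2] = centre[2]  # exact: the bounding box has zero z extent
    return pts


def _wall_base_points(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed wall points: two side walls, floor, ceiling, back wall."""
    half_w = config.arena_extent[0] / 2.0
    half_h = config.arena_extent[1] / 2.0
    depth = config.arena_extent[2]
    faces = [
        ("x", -half_w), ("x", half_w),
        ("y", -half_h), ("y", half_h),
        ("z", depth),
    ]
    chunks = []
    for axis, coord in faces:
        if axis == "z":
            area = config.arena_extent[0] * config.arena_extent[1]
        else:
            area = (config.arena_extent[1] if axis == "x" else config.arena_extent[0]) * depth
        n = int(round(config.background_density * area))
        if n == 0:
            continue
        # surface roughness: 1–4 mm proud of the wall plane, toward the arena
        inward = -np.sign(coord) * rng.uniform(0.001, 0.004, size=n)
        perp = coord + inward
        if axis == "x":
            pts = np.column_stack([perp, rng.uniform(-half_h, half_h, n), rng.uniform(0, depth, n)])
        elif axis == "y":
            pts = np.column_stack([rng.uniform(-half_w, half_w, n), perp, rng.uniform(0, depth, n)])
        else:
            pts = np.column_stack([rng.uniform(-half_w, half_w, n), rng.uniform(-half_h, half_h, n), perp])
        chunks.append(pts)
    base = np.vstack(chunks) if chunks else np.zeros((0, 3))
    # clip once with a jitter-sized margin so jittered points never flicker
    # in and out of the field of view across frames
    return base[_frustum_mask(base, config, margin=2.0 * config.background_jitter_m)]


def simulate_scene(config: SceneConfig) -> tuple[FrameSequence, SceneTruth]:
    """Render one labelled scene; identical seeds give identical output."""
    rng = np.random.default_rng(config.rng_seed)
    dt = 1.0 / config.frame_rate_fps

    base_walls = _wall_base_points(config, rng)

    boxes = _moth_boxes(config)
    moth_paths: dict[int, np.ndarray] = {}
    for m in range(config.n_moths):
        moth_paths[m + 1] = sample_moth_path(
            config.n_frames, rng, boxes[m],
            speed_mean_mps=config.moth_speed_mean_mps,
            speed_sd_mps=config.moth_speed_sd_mps,
            dt_s=dt,
            max_turn_deg=config.max_turn_deg,
            heading_sigma=config.heading_sigma,
        )

    tan_h = math.tan(math.radians(config.fov_h_deg / 2.0))
    tan_v = math.tan(math.radians(config.fov_v_deg / 2.0))
    events: dict[int, NoiseEvent] = {}
    for k in range(config.n_noise_events):
        kind = "transient_blob" if k % 2 == 0 else "coplanar_artifact"
        if kind == "transient_blob":
            lifetime = int(rng.integers(1, 61))
            z = rng.uniform(0.6, 3.2)
            base = np.array([
                rng.uniform(-(z * tan_h - 0.1), z * tan_h - 0.1),
                rng.uniform(-(z * tan_v - 0.1), z * tan_v - 0.1),
                z,
            ])
            positions = sample_noise_path(lifetime, rng, base=base)
        else:
            lifetime = int(rng.integers(10, 61))
            z = config.near_range_m + rng.uniform(-0.05, 0.05)
            base = np.array([rng.uniform(-0.2, 0.2), rng.uniform(-0.15, 0.15), z])
            positions = sample_noise_path(lifetime, rng, base=base)
            positions[:, 2] = z  # in-plane motion only
        start = int(rng.integers(0, max(config.n_frames - lifetime, 1)))
        events[k] = NoiseEvent(event_id=k, kind=kind, start_frame=start, positions=positions)

    frames: list[FrameCloud] = []
    labels: list[np.ndarray] = []
    plo, phi = config.moth_points_range
    nlo, nhi = config.noise_points_range
    for t in range(config.n_frames):
        chunks: list[np.ndarray] = []
        chunk_labels: list[np.ndarray] = []
        if base_walls.shape[0]:
            jitter = rng.uniform(
                -config.background_jitter_m, config.background_jitter_m, size=base_walls.shape
            )
            wall_pts = base_walls + jitter
            chunks.append(wall_pts)
            chunk_labels.append(np.full(wall_pts.shape[0], LABEL_BACKGROUND, dtype=np.int64))
        for m in sorted(moth_paths):
            # moths are released around recording start and reach the field of
            # view after the background-training frames, so the initial frames
            # show only the static scene (plus any transient artifacts)
            if t < config.moth_entry_frame:
                continue
            n_pts = int(rng.integers(plo, phi + 1))
            blob = render_moth_blob(moth_paths[m][t], n_pts, config.moth_spread_m, rng)
            mask = _frustum_mask(blob, config)
            blob = blob[mask]
            chunks.append(blob)
            chunk_labels.append(np.full(blob.shape[0], m, dtype=np.int64))
        for k, ev in events.items():
            if t not in ev.frames:
                continue
            centre = ev.positions[t - ev.start_frame]
            n_pts = int(rng.integers(nlo, nhi + 1))
            if ev.kind == "coplanar_artifact":
                blob = _render_coplanar_blob(centre, n_pts, 0.02, rng)
            else:
                blob = render_moth_blob(centre, n_pts, 0.015, rng)
            mask = _frustum_mask(blob, config)
            blob = blob[mask]
            chunks.append(blob)
            chunk_labels.append(np.full(blob.shape[0], -(k + 1), dtype=np.int64))
        pts = np.vstack(chunks) if chunks else np.zeros((0, 3))
        frames.append(FrameCloud(frame_index=t, points=pts, timestamp_s=t * dt))
        labels.append(np.concatenate(chunk_labels) if chunk_labels else np.zeros(0, dtype=np.int64))

    sequence = FrameSequence(frames=frames, frame_rate_fps=config.frame_rate_fps)
    truth = SceneTruth(labels=labels, moth_paths=moth_paths, noise_events=events)
    return sequence, truth
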