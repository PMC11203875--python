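"""Frame-sequence (PLY) and trajectory (CSV) input/output.

Point clouds live in the camera frame: origin at the stereo camera,
+Z pointing away from the camera (depth), +X right, +Y up, coordinates
in metres.  A recording is a directory of per-frame PLY files whose
names embed consecutive integer frame indices (``frame_0000.ply`` ...).

The PLY codec here is deliberately narrow: it reads ``ascii`` and
``binary_little_endian`` files whose vertex element carries scalar
``x``/``y``/``z`` properties (extra scalar vertex properties are
ignored) and it writes binary little-endian float32 vertices.  That is
the dialect stereo-vision exports and ParaView produce for raw point
clouds; faces and list properties are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FrameCloud",
    "FrameSequence",
    "SequenceGapError",
    "read_ply",
    "write_ply",
    "read_frame_sequence",
    "write_frame_sequence",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "TRAJECTORY_CSV_COLUMNS",
]

DEFAULT_FRAME_RATE_FPS = 55.0


class SequenceGapError(ValueError):
    """Raised when frame indices in a recording are not consecutive."""


@dataclass(frozen=True)
class FrameCloud:
    """One frame's 3D points (metres, camera coordinates)."""

    frame_index: int
    points: np.ndarray  # (N, 3) float64
    timestamp_s: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            pts = pts.reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if pts.size and not np.isfinite(pts).all():
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class FrameSequence:
    """Time-ordered frames at a fixed frame rate.

    Frame indices must be consecutive starting at 0; a gap in the
    recording is an input error, not a condition the tracker handles.
    """

    frames: list[FrameCloud] = field(default_factory=list)
    frame_rate_fps: float = DEFAULT_FRAME_RATE_FPS

    def __post_init__(self) -> None:
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be positive")
        indices = [f.frame_index for f in self.frames]
        if indices != list(range(len(indices))):
            raise SequenceGapError(
                f"frame indices must be consecutive from 0, got {indices[:10]}..."
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> FrameCloud:
        return self.frames[i]


# ---------------------------------------------------------------------------
# PLY codec

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def read_ply(path: str | Path) -> np.ndarray:
    """Read vertex x/y/z from an ascii or binary little-endian PLY file.

    Returns an (N, 3) float64 array; N may be 0.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise ValueError(f"{path}: property before element")
                if tokens[1] == "list":
                    elements[-1][2].append(("list", tokens[-1]))
                else:
                    elements[-1][2].append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {fmt!r}")
        vertex_spec = next((e for e in elements if e[0] == "vertex"), None)
        if vertex_spec is None:
            raise ValueError(f"{path}: no vertex element")
        if elements.index(vertex_spec) != 0 and any(
            p[0] == "list" for e in elements[: elements.index(vertex_spec)] for p in e[2]
        ):
            raise ValueError(f"{path}: list properties before vertex element unsupported")

        def read_element(count: int, props: list[tuple[str, str]]) -> np.ndarray | None:
            if any(p[0] == "list" for p in props):
                raise ValueError(f"{path}: list property in a scalar element")
            if fmt == "ascii":
                rows = [fh.readline().split() for _ in range(count)]
                arr = np.array(rows, dtype=np.float64) if count else np.zeros((0, len(props)))
                return arr
            dtype = np.dtype([(name, "<" + _PLY_DTYPES[t]) for t, name in props])
            buf = fh.read(dtype.itemsize * count)
            if len(buf) != dtype.itemsize * count:
                raise ValueError(f"{path}: truncated PLY body")
            rec = np.frombuffer(buf, dtype=dtype)
            return np.column_stack([rec[name].astype(np.float64) for _, name in props])

        for name, count, props in elements:
            data = read_element(count, props)
            if name == "vertex":
                names = [p[1] for p in props]
                try:
                    cols = [names.index(c) for c in ("x", "y", "z")]
                except ValueError:
                    raise ValueError(f"{path}: vertex element lacks x/y/z") from None
                return np.ascontiguousarray(data[:, cols]) if count else np.zeros((0, 3))
        raise AssertionError("unreachable")


def write_ply(points: np.ndarray, path: str | Path) -> None:
    """Write an (N, 3) array as a binary little-endian float32 PLY."""
    pts = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {pts.shape[0]}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(pts, dtype="<f4").tobytes())


_FRAME_INDEX_RE = re.compile(r"(\d+)(?!.*\d)")  # last integer run in the stem


def read_frame_sequence(
    directory_path: str | Path,
    frame_rate: float = DEFAULT_FRAME_RATE_FPS,
) -> FrameSequence:
    """Load a directory of per-frame PLY files into a FrameSequence.

    Files are ordered by the last integer embedded in each filename;
    indices must be consecutive (a gap raises SequenceGapError).
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such frame directory: {directory}")
    entries: list[tuple[int, Path]] = []
    for p in sorted(directory.glob("*.ply")):
        m = _FRAME_INDEX_RE.search(p.stem)
        if m is None:
            raise ValueError(f"{p.name}: no frame index in filename")
        entries.append((int(m.group(1)), p))
    if not entries:
        raise FileNotFoundError(f"{directory}: no PLY files")
    entries.sort(key=lambda e: e[0])
    indices = [e[0] for e in entries]
    if len(set(indices)) != len(indices):
        raise SequenceGapError(f"{directory}: duplicate frame indices")
    lo = indices[0]
    if indices != list(range(lo, lo + len(indices))):
        missing = sorted(set(range(lo, indices[-1] + 1)) - set(indices))
        raise SequenceGapError(f"{directory}: missing frame indices {missing[:10]}")
    frames = [
        FrameCloud(frame_index=idx - lo, points=read_ply(p), timestamp_s=(idx - lo) / frame_rate)
        for idx, p in entries
    ]
    return FrameSequence(frames=frames, frame_rate_fps=frame_rate)


def write_frame_sequence(sequence: FrameSequence, directory_path: str | Path) -> list[Path]:
    """Write each frame as ``frame_NNNN.ply`` under ``directory_path``."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame in sequence:
        p = directory / f"frame_{frame.frame_index:04d}.ply"
        write_ply(frame.points, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Trajectory CSV

TRAJECTORY_CSV_COLUMNS = [
    "frame_index",
    "centroid_x",
    "centroid_y",
    "centroid_z",
    "point_count",
    "obv_m3",
    "speed_mps",
    "turning_angle_deg",
    "distance_from_camera_m",
    "density_pts_per_m3",
]


def write_trajectory_csv(trajectory, path: str | Path, frame_rate_fps: float | None = None) -> None:
    """Export one trajectory as a per-frame CSV table.

    One row per frame.  ``speed_mps`` is empty on the first frame and
    ``turning_angle_deg`` on the first two frames (both are backward
    differences); ``density_pts_per_m3`` is empty where the outline-box
    volume is zero.  Values round-trip at 12 significant digits.
    """
    from .kinematics import trajectory_table

    if len(trajectory.detections) < 1:
        raise ValueError("cannot export an empty trajectory")
    fps = frame_rate_fps if frame_rate_fps is not None else DEFAULT_FRAME_RATE_FPS
    table = trajectory_table(trajectory, fps)
    table.to_csv(path, index=False, float_format="%.12g", na_rep="")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory CSV columns {missing}")
    return df
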