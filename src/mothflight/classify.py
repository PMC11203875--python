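"""Linear-SVM moth/noise classification of candidate trajectories.

Two features summarise the last 10 tracked frames of a candidate:

* ``sd_position_m`` — scalar spatial standard deviation of the centroid
  positions (RMS distance from the window-mean centroid).  Real flight
  covers ground, so this is large; stationary noise blobs score near 0.
* ``sd_turning_deg`` — population standard deviation of the turning
  angles between consecutive displacement vectors (0° = straight,
  180° = reversal).  Smooth flight keeps headings consistent; transient
  stereo noise jitters between near-reversals.

A linear maximum-margin classifier on the standardised features
separates the two regimes.  No trained weights ship with the camera
system, so the model is fitted on labelled synthetic trajectories
(see :mod:`mothflight.simulate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.svm import LinearSVC

__all__ = [
    "TrajectoryFeatures",
    "LinearModel",
    "turning_angles_deg",
    "extract_features",
    "train_classifier",
    "classify",
]

DEFAULT_WINDOW_FRAMES = 10


def turning_angles_deg(centroids: np.ndarray) -> np.ndarray:
    """Turning angle at each frame t >= 2, from c_{t-2}, c_{t-1}, c_t.

    The angle is between the previous displacement (c_{t-1} - c_{t-2})
    and the current one (c_t - c_{t-1}); 0° means straight flight,
    180° a full reversal.  A zero-length displacement contributes a 0°
    angle by convention (the direction is undefined).
    """
    c = np.asarray(centroids, dtype=np.float64)
    if c.shape[0] < 3:
        return np.zeros(0)
    d = np.diff(c, axis=0)
    u, v = d[:-1], d[1:]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > 0) & (nv > 0)
    cosang = np.ones(len(u))
    cosang[ok] = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


@dataclass(frozen=True)
class TrajectoryFeatures:
    sd_position_m: float
    sd_turning_deg: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sd_position_m, self.sd_turning_deg])


def extract_features(
    trajectory,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    position_sd_mode: Literal["scalar", "per_axis_norm"] = "scalar",
) -> TrajectoryFeatures:
    """Features over the final ``window_frames`` detections.

    ``scalar`` mode (default) uses the RMS distance from the window
    mean; ``per_axis_norm`` uses the Euclidean norm of the three
    per-axis population SDs, provided for sensitivity checks (the two
    agree up to the cross-axis covariance structure).
    """
    centroids = trajectory.centroids if hasattr(trajectory, "centroids") else np.asarray(trajectory)
    if centroids.shape[0] < window_frames:
        raise ValueError(
            f"trajectory has {centroids.shape[0]} frames, need >= {window_frames}"
        )
    window = centroids[-window_frames:]
    mean = window.mean(axis=0)
    if position_sd_mode == "scalar":
        sd_pos = float(np.sqrt(np.mean(np.sum((window - mean) ** 2, axis=1))))
    elif position_sd_mode == "per_axis_norm":
        sd_pos = float(np.linalg.norm(window.std(axis=0, ddof=0)))
    else:
        raise ValueError(f"unknown position_sd_mode {position_sd_mode!r}")
    angles = turning_angles_deg(window)
    sd_turn = float(angles.std(ddof=0)) if angles.size else 0.0
    return TrajectoryFeatures(sd_position_m=sd_pos, sd_turning_deg=sd_turn)


@dataclass
class LinearModel:
    """Standardised linear decision rule: moth iff w . z + b > 0."""

    weights: np.ndarray        # (2,)
    bias: float
    feature_means: np.ndarray  # (2,)
    feature_sds: np.ndarray    # (2,)

    def decision_value(self, features: TrajectoryFeatures | np.ndarray) -> float:
        x = features.as_array() if isinstance(features, TrajectoryFeatures) else np.asarray(features)
        z = (x - self.feature_means) / self.feature_sds
        return float(self.weights @ z + self.bias)

    def predict(self, features: TrajectoryFeatures | np.ndarray) -> str:
        # a decision value of exactly 0 is labelled noise (conservative)
        return "moth" if self.decision_value(features) > 0 else "noise"

    def to_json(self, path: str | Path | None = None) -> str:
        record = {
            "w1": float(self.weights[0]),
            "w2": float(self.weights[1]),
            "b": float(self.bias),
            "feature_means": [float(v) for v in self.feature_means],
            "feature_sds": [float(v) for v in self.feature_sds],
        }
        text = json.dumps(record, sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LinearModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        record = json.loads(text)
        return cls(
            weights=np.array([record["w1"], record["w2"]], dtype=np.float64),
            bias=float(record["b"]),
            feature_means=np.array(record["feature_means"], dtype=np.float64),
            feature_sds=np.array(record["feature_sds"], dtype=np.float64),
        )


def train_classifier(
    features: Sequence[TrajectoryFeatures] | np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    C: float = 1.0,
) -> LinearModel:
    """Fit the linear max-margin moth/noise model on standardised features.

    Deterministic: the primal solver is used, so refitting the same data
    yields identical weights.
    """
    X = np.array(
        [f.as_array() if isinstance(f, TrajectoryFeatures) else np.asarray(f) for f in features],
        dtype=np.float64,
    )
    y = np.array([1 if lab == "moth" else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both moth and noise examples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds < 1e-12, 1.0, sds)
    Z = (X - means) / sds
    svc = LinearSVC(C=C, dual=False, random_state=seed, max_iter=10000)
    svc.fit(Z, y)
    return LinearModel(
        weights=svc.coef_[0].astype(np.float64),
        bias=float(svc.intercept_[0]),
        feature_means=means,
        feature_sds=sds,
    )


def classify(
    trajectory,
    model: LinearModel,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    mode: Literal["final", "sliding"] = "final",
) -> str:
    """Label one trajectory ``moth`` or ``noise``.

    ``final`` (default) classifies the last window once; ``sliding``
    mimics the online system, labelling the trajectory noise if any
    length-``window_frames`` window classifies as noise.
    """
    centroids = trajectory.centroids
    if mode == "final":
        return model.predict(extract_features(trajectory, window_frames))
    if mode != "sliding":
        raise ValueError(f"unknown mode {mode!r}")
    for end in range(window_frames, centroids.shape[0] + 1):
        feats = extract_features(centroids[:end], window_frames)
        if model.predict(feats) == "noise":
            return "noise"
    return "moth"
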