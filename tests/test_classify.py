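import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from mothflight import (
    LinearModel,
    classify,
    extract_features,
    train_classifier,
    turning_angles_deg,
)
from mothflight.simulate import make_training_paths
from conftest import traj_from_centroids


def features_by_hand(centroids):
    """Independent recomputation of both features from their definitions."""
    window = np.asarray(centroids, dtype=float)
    mean = window.mean(axis=0)
    sd_pos = math.sqrt(np.mean([np.dot(c - mean, c - mean) for c in window]))
    angles = []
    for t in range(2, len(window)):
        u = window[t - 1] - window[t - 2]
        v = window[t] - window[t - 1]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            angles.append(0.0)
        else:
            angles.append(math.degrees(math.acos(np.clip(np.dot(u, v) / (nu * nv), -1, 1))))
    sd_turn = float(np.std(angles)) if angles else 0.0
    return sd_pos, sd_turn


class TestTurningAngles:
    def test_collinear_motion_gives_zero(self):
        c = np.array([[0, 0, 2.0], [0.01, 0, 2.0], [0.02, 0, 2.0]])
        np.testing.assert_allclose(turning_angles_deg(c), [0.0], atol=1e-9)

    def test_reversal_gives_180(self):
        c = np.array([[0, 0, 2.0], [0.01, 0, 2.0], [0.0, 0, 2.0]])
        np.testing.assert_allclose(turning_angles_deg(c), [180.0])

    def test_right_angle(self):
        c = np.array([[0, 0, 2.0], [0.01, 0, 2.0], [0.01, 0.01, 2.0]])
        np.testing.assert_allclose(turning_angles_deg(c), [90.0])

    def test_zero_displacement_contributes_zero_angle(self):
        c = np.array([[0, 0, 2.0], [0, 0, 2.0], [0.01, 0, 2.0]])
        np.testing.assert_allclose(turning_angles_deg(c), [0.0])


class TestExtractFeatures:
    def test_stationary_trajectory_degenerate_features(self):
        traj = traj_from_centroids(np.tile([[0.1, 0.2, 1.0]], (10, 1)))
        f = extract_features(traj, 10)
        assert f.sd_position_m == pytest.approx(0.0, abs=1e-15)
        assert f.sd_turning_deg == 0.0

    def test_straight_constant_velocity(self):
        path = np.array([[0, 0, 2.0] + i * np.array([0.02, 0, 0]) for i in range(10)])
        f = extract_features(traj_from_centroids(path), 10)
        assert f.sd_turning_deg == pytest.approx(0.0, abs=1e-9)
        assert f.sd_position_m > 0

    def test_matches_hand_recomputation_on_frozen_path(self):
        rng = np.random.default_rng(12)
        path = np.cumsum(rng.normal(scale=0.02, size=(10, 3)), axis=0) + [0, 0, 2.0]
        f = extract_features(traj_from_centroids(path), 10)
        sd_pos, sd_turn = features_by_hand(path)
        assert f.sd_position_m == pytest.approx(sd_pos, rel=1e-12)
        assert f.sd_turning_deg == pytest.approx(sd_turn, rel=1e-12)

    def test_uses_final_window_only(self):
        head = np.tile([[5.0, 5.0, 5.0]], (7, 1))
        tail = np.cumsum(np.full((10, 3), 0.01), axis=0)
        f_full = extract_features(traj_from_centroids(np.vstack([head, tail])), 10)
        f_tail = extract_features(traj_from_centroids(tail), 10)
        assert f_full == f_tail

    def test_short_trajectory_raises(self):
        with pytest.raises(ValueError):
            extract_features(traj_from_centroids(np.zeros((5, 3))), 10)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(scale=0.02, size=(10, 3)), axis=0)
        R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
        shift = rng.uniform(-2, 2, 3)
        moved = path @ R.T + shift
        f0 = extract_features(traj_from_centroids(path), 10)
        f1 = extract_features(traj_from_centroids(moved), 10)
        assert f1.sd_position_m == pytest.approx(f0.sd_position_m, rel=1e-9)
        assert f1.sd_turning_deg == pytest.approx(f0.sd_turning_deg, rel=1e-9, abs=1e-9)


class TestTrainClassifier:
    def make_separable(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        moth = np.column_stack([rng.uniform(0.05, 0.15, n), rng.uniform(0, 20, n)])
        noise = np.column_stack([rng.uniform(0.0, 0.01, n), rng.uniform(60, 180, n)])
        X = np.vstack([moth, noise])
        y = ["moth"] * n + ["noise"] * n
        return X, y

    def test_training_accuracy_100_on_separable_set(self):
        X, y = self.make_separable()
        model = train_classifier(X, y, seed=0)
        preds = [model.predict(x) for x in X]
        assert preds == y

    def test_single_class_raises(self):
        X = np.random.default_rng(0).uniform(size=(20, 2))
        with pytest.raises(ValueError):
            train_classifier(X, ["moth"] * 20, seed=0)

    def test_refit_same_seed_identical_weights(self):
        X, y = self.make_separable()
        m1 = train_classifier(X, y, seed=3)
        m2 = train_classifier(X, y, seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert m1.bias == m2.bias

    def test_model_json_round_trip(self, tmp_path):
        X, y = self.make_separable()
        model = train_classifier(X, y, seed=0)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = LinearModel.from_json(p)
        np.testing.assert_array_equal(back.weights, model.weights)
        record = json.loads(p.read_text())
        assert set(record) == {"w1", "w2", "b", "feature_means", "feature_sds"}

    def test_decision_value_zero_is_noise(self):
        model = LinearModel(
            weights=np.array([1.0, 0.0]),
            bias=0.0,
            feature_means=np.zeros(2),
            feature_sds=np.ones(2),
        )
        assert model.predict(np.array([0.0, 0.0])) == "noise"
        assert model.predict(np.array([0.1, 0.0])) == "moth"


class TestClassifyTrajectories:
    def test_holdout_accuracy_on_simulated_paths(self):
        train_paths, train_labels = make_training_paths(100, seed=0)
        test_paths, test_labels = make_training_paths(100, seed=1)
        feats = [extract_features(p, 10) for p in train_paths]
        model = train_classifier(feats, train_labels, seed=0)
        preds = [model.predict(extract_features(p, 10)) for p in test_paths]
        acc = np.mean([p == t for p, t in zip(preds, test_labels)])
        assert acc >= 0.95

    def test_classify_modes(self):
        train_paths, train_labels = make_training_paths(100, seed=0)
        feats = [extract_features(p, 10) for p in train_paths]
        model = train_classifier(feats, train_labels, seed=0)
        moth_path = train_paths[0]
        traj = traj_from_centroids(moth_path)
        assert classify(traj, model, 10, mode="final") == "moth"
        assert classify(traj, model, 10, mode="sliding") in ("moth", "noise")
        with pytest.raises(ValueError):
            classify(traj, model, 10, mode="bogus")
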