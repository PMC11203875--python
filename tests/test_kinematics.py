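import math

import numpy as np
import pytest

from mothflight import (
    compute_kinematics,
    filter_turning_angle,
    filter_zero_obv,
    iqr_outlier_screen,
    noise_proxy,
    summarize,
)
from mothflight.simulate import sample_moth_path, sample_noise_path
from conftest import traj_from_centroids


class TestComputeKinematics:
    def test_speed_hand_computation(self):
        traj = traj_from_centroids(np.array([[0, 0, 2.0], [0.03, 0, 2.01]]))
        kin = compute_kinematics(traj, 55.0)
        assert math.isnan(kin[0].speed_mps)
        assert kin[1].speed_mps == pytest.approx(55 * math.sqrt(0.0009 + 0.0001), rel=1e-12)
        assert kin[1].speed_mps == pytest.approx(1.739, abs=0.001)

    def test_collinear_equal_spacing_angle_zero(self):
        traj = traj_from_centroids(np.array([[0, 0, 2.0], [0.02, 0, 2.0], [0.04, 0, 2.0]]))
        kin = compute_kinematics(traj, 55.0)
        assert kin[2].turning_angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_reversal_angle_180(self):
        traj = traj_from_centroids(np.array([[0, 0, 2.0], [0.02, 0, 2.0], [0, 0, 2.0]]))
        kin = compute_kinematics(traj, 55.0)
        assert kin[2].turning_angle_deg == pytest.approx(180.0)

    def test_length_one_raises(self):
        with pytest.raises(ValueError):
            compute_kinematics(traj_from_centroids(np.zeros((1, 3))), 55.0)

    def test_undefined_entries_are_nan_not_zero(self):
        traj = traj_from_centroids(
            np.array([[0, 0, 2.0], [0.02, 0, 2.0], [0.04, 0, 2.0]]),
            extents=[(0.04, 0.04, 0.04), (0.04, 0.04, 0.0), (0.04, 0.04, 0.04)],
        )
        kin = compute_kinematics(traj, 55.0)
        assert math.isnan(kin[0].speed_mps)
        assert math.isnan(kin[0].turning_angle_deg) and math.isnan(kin[1].turning_angle_deg)
        assert kin[1].obv_m3 == 0.0 and math.isnan(kin[1].density_pts_per_m3)
        assert kin[2].density_pts_per_m3 == pytest.approx(50 / 0.04**3)

    def test_distance_from_camera_is_centroid_norm(self):
        traj = traj_from_centroids(np.array([[0.3, 0.4, 0.0], [0.3, 0.4, 0.1]]))
        kin = compute_kinematics(traj, 55.0)
        assert kin[0].distance_from_camera_m == pytest.approx(0.5)


def straight_traj(n=12, start=(0, 0, 2.0), step=(0.02, 0, 0), tid=0, extents=(0.04, 0.04, 0.04)):
    path = np.array([np.array(start, dtype=float) + i * np.array(step) for i in range(n)])
    return traj_from_centroids(path, extents=extents, trajectory_id=tid)


class TestZeroObvFilter:
    def test_coplanar_frame_removes_trajectory(self):
        extents = [(0.04, 0.04, 0.04)] * 12
        extents[5] = (0.04, 0.04, 0.0)
        bad = traj_from_centroids(
            np.array([[i * 0.02, 0, 0.9] for i in range(12)]), extents=extents, trajectory_id=1
        )
        good = straight_traj(tid=0)
        kept, removed = filter_zero_obv([good, bad])
        assert [t.trajectory_id for t in kept] == [0]
        assert [t.trajectory_id for t in removed] == [1]
        # the artifact sits near the camera's minimum effective range
        assert removed[0].detections[5].distance_from_camera_m == pytest.approx(0.9, abs=0.15)

    def test_generic_blob_kept(self):
        kept, removed = filter_zero_obv([straight_traj()])
        assert len(kept) == 1 and removed == []

    def test_kept_plus_removed_is_input(self):
        trajs = [straight_traj(tid=i) for i in range(5)]
        kept, removed = filter_zero_obv(trajs)
        assert len(kept) + len(removed) == 5


class TestTurningAngleFilter:
    def make_with_turn(self, angle_deg, tid=0):
        # straight run, then one turn of exactly angle_deg, then straight
        step = 0.02
        heading = np.array([1.0, 0, 0])
        a = math.radians(angle_deg)
        turned = np.array([math.cos(a), math.sin(a), 0.0])
        path = [np.array([0, 0, 2.0])]
        for _ in range(5):
            path.append(path[-1] + step * heading)
        for _ in range(5):
            path.append(path[-1] + step * turned)
        return traj_from_centroids(np.array(path), trajectory_id=tid)

    def test_120_degree_turn_removed(self):
        kept, removed = filter_turning_angle([self.make_with_turn(120.0)], 110.0)
        assert kept == [] and len(removed) == 1

    def test_exactly_110_kept_strict_inequality(self):
        kept, removed = filter_turning_angle([self.make_with_turn(110.0)], 110.0)
        assert len(kept) == 1 and removed == []

    def test_cutoff_180_removes_nothing(self):
        trajs = [self.make_with_turn(a, i) for i, a in enumerate([30, 120, 175])]
        kept, removed = filter_turning_angle(trajs, 180.0)
        assert len(kept) == 3 and removed == []

    def test_cutoff_0_removes_any_noncollinear(self):
        trajs = [self.make_with_turn(30.0, 0), straight_traj(tid=1)]
        kept, removed = filter_turning_angle(trajs, 0.0)
        assert [t.trajectory_id for t in kept] == [1]
        assert [t.trajectory_id for t in removed] == [0]

    def test_simulated_reciprocating_blob_removed(self):
        rng = np.random.default_rng(3)
        path = sample_noise_path(15, rng, base=np.array([0.1, 0.0, 1.2]))
        kept, removed = filter_turning_angle([traj_from_centroids(path)], 110.0)
        assert kept == [] and len(removed) == 1


class TestIqrScreen:
    def moth_cohort(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        box = (np.array([-0.5, -0.35, 1.5]), np.array([0.5, 0.35, 3.2]))
        return [
            traj_from_centroids(sample_moth_path(30, rng, box), trajectory_id=i)
            for i in range(n)
        ]

    def planted_noise(self, n=3, seed=1, tid0=100):
        rng = np.random.default_rng(seed)
        return [
            traj_from_centroids(
                sample_noise_path(20, rng, base=np.array([0.2, 0.1, 1.0])),
                trajectory_id=tid0 + i,
            )
            for i in range(n)
        ]

    def test_identical_trajectories_all_kept(self):
        trajs = [straight_traj(tid=i) for i in range(6)]
        kept, removed = iqr_outlier_screen(trajs)
        assert len(kept) == 6 and removed == []

    def test_planted_high_turning_noise_removed_exactly(self):
        trajs = self.moth_cohort() + self.planted_noise()
        kept, removed = iqr_outlier_screen(trajs)
        assert sorted(t.trajectory_id for t in removed) == [100, 101, 102]
        assert len(kept) == 20

    def test_fewer_than_four_is_noop(self):
        trajs = self.planted_noise(n=3)
        kept, removed = iqr_outlier_screen(trajs)
        assert len(kept) == 3 and removed == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_removal_monotone_in_fence_k(self, seed):
        trajs = self.moth_cohort(seed=seed) + self.planted_noise(seed=seed + 50)
        _, removed_tight = iqr_outlier_screen(trajs, fence_k=1.0)
        _, removed_loose = iqr_outlier_screen(trajs, fence_k=2.0)
        tight_ids = {t.trajectory_id for t in removed_tight}
        loose_ids = {t.trajectory_id for t in removed_loose}
        assert loose_ids <= tight_ids

    def test_trim_mode_keeps_clean_core(self):
        rng = np.random.default_rng(9)
        box = (np.array([-0.5, -0.35, 1.5]), np.array([0.5, 0.35, 3.2]))
        cohort = self.moth_cohort()
        # a flight segment bracketed by reciprocating noise at the end
        flight = sample_moth_path(25, rng, box)
        tail = sample_noise_path(6, rng, base=flight[-1])
        mixed = traj_from_centroids(np.vstack([flight, tail]), trajectory_id=200)
        kept, removed = iqr_outlier_screen(
            cohort + [mixed], mode="trim", confirm=lambda t: True, min_length_frames=10
        )
        trimmed = [t for t in kept if t.trajectory_id == 200]
        assert trimmed and len(trimmed[0]) < 31


class TestNoiseProxy:
    def test_low_net_displacement_is_noise(self):
        rng = np.random.default_rng(0)
        traj = traj_from_centroids(sample_noise_path(20, rng, base=np.array([0, 0, 1.0])))
        assert noise_proxy(traj)

    def test_travelling_trajectory_is_not_noise(self):
        assert not noise_proxy(straight_traj(n=15))

    def test_frame_gap_is_noise(self):
        path = np.array([[i * 0.02, 0, 2.0] for i in range(12)])
        traj = traj_from_centroids(path, frame_indices=[0, 1, 2, 3, 4, 5, 7, 8, 9, 10, 11, 12])
        assert noise_proxy(traj)


class TestSummarize:
    def test_constant_speed_trajectory(self):
        traj = straight_traj(n=10)
        stats = summarize([traj], 55.0)
        v = 0.02 * 55
        assert stats.speed_mean_mps == pytest.approx(v)
        assert stats.speed_median_mps == pytest.approx(v)
        assert stats.speed_sd_mps == pytest.approx(0.0, abs=1e-12)
        assert stats.n_trajectories == 1

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(17)
        trajs = [
            traj_from_centroids(np.cumsum(rng.normal(scale=0.02, size=(15, 3)), axis=0), trajectory_id=i)
            for i in range(3)
        ]
        stats = summarize(trajs, 55.0)
        # oracle: pool speeds by hand
        pooled = []
        for t in trajs:
            c = t.centroids
            for a, b in zip(c[:-1], c[1:]):
                pooled.append(float(np.linalg.norm(b - a)) * 55.0)
        pooled = np.array(pooled)
        assert stats.n_speed_samples == len(pooled)
        assert stats.speed_mean_mps == pytest.approx(pooled.mean(), rel=1e-12)
        assert stats.speed_median_mps == pytest.approx(np.median(pooled), rel=1e-12)
        assert stats.speed_q1_mps <= stats.speed_median_mps <= stats.speed_q3_mps

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize([], 55.0)
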