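import numpy as np
import pytest

from usimgen import reach
from usimgen.dataset import Annotation
from usimgen.errors import (
    DegenerateConfigurationError,
    ProjectionError,
    UnderdeterminedError,
)


def _random_homography(rng):
    """Well-conditioned random projective map."""
    while True:
        h = np.eye(3) + rng.normal(0, 0.3, (3, 3))
        h[2, :2] = rng.normal(0, 1e-3, 2)  # mild perspective
        if abs(np.linalg.det(h)) > 1e-3:
            return h / h[2, 2]


def _pairs_from_h(h, n, rng, noise=0.0):
    world = rng.uniform(-50, 50, (n, 2))
    hom = np.column_stack([world, np.ones(n)]) @ h.T
    img = hom[:, :2] / hom[:, 2:3]
    img = img + rng.normal(0, noise, img.shape)
    return [reach.PointPair(tuple(w), tuple(i)) for w, i in zip(world, img)]


class TestEstimateHomography:
    def test_identity_from_identical_points(self):
        pts = [(0, 0), (10, 0), (0, 10), (7, 13)]
        pairs = [reach.PointPair(p, p) for p in pts]
        h = reach.estimate_homography(pairs)
        np.testing.assert_allclose(h.matrix, np.eye(3), atol=1e-9)

    def test_recovers_diagonal_scaling(self):
        rng = np.random.default_rng(0)
        h_true = np.diag([2.0, 2.0, 1.0])
        pairs = _pairs_from_h(h_true, 6, rng)
        h = reach.estimate_homography(pairs)
        np.testing.assert_allclose(h.matrix, h_true, atol=1e-8)

    def test_noiseless_recovery_random_homographies(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            h_true = _random_homography(rng)
            pairs = _pairs_from_h(h_true, 8, rng)
            h = reach.estimate_homography(pairs)
            rel = np.abs(h.matrix - h_true).max() / np.abs(h_true).max()
            assert rel < 1e-8

    def test_noise_consistency(self):
        """Reprojection RMSE tracks the injected image noise."""
        rng = np.random.default_rng(2)
        sigma = 0.5
        rmses = []
        h_true = _random_homography(rng)
        for _ in range(100):
            pairs = _pairs_from_h(h_true, 12, rng, noise=sigma)
            h = reach.estimate_homography(pairs)
            rmses.append(reach.reprojection_rmse(h, pairs))
        mean_rmse = float(np.mean(rmses))
        assert 0.5 * sigma <= mean_rmse <= 2.0 * sigma

    def test_too_few_pairs(self):
        pairs = [reach.PointPair((0, 0), (0, 0))] * 3
        with pytest.raises(UnderdeterminedError):
            reach.estimate_homography(pairs)

    def test_collinear_points_rejected(self):
        pairs = [
            reach.PointPair((i, 2 * i), (i, 2 * i)) for i in range(6)
        ]
        with pytest.raises(DegenerateConfigurationError):
            reach.estimate_homography(pairs)


class TestProject:
    def test_identity(self):
        h = reach.Homography(np.eye(3))
        np.testing.assert_allclose(reach.project(h, (3.5, -2.0)), [3.5, -2.0])

    def test_translation(self):
        m = np.eye(3)
        m[0, 2], m[1, 2] = 5.0, -3.0
        h = reach.Homography(m)
        np.testing.assert_allclose(reach.project(h, (0, 0)), [5.0, -3.0])

    def test_matches_homogeneous_algebra_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = _random_homography(rng)
            h = reach.Homography(m)
            p = rng.uniform(-20, 20, 2)
            v = m @ np.array([p[0], p[1], 1.0])
            np.testing.assert_allclose(reach.project(h, p), v[:2] / v[2], rtol=1e-12)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(4)
        m = _random_homography(rng)
        h = reach.Homography(m)
        p = np.array([7.0, -11.0])
        back = reach.project(h.inverse(), reach.project(h, p))
        np.testing.assert_allclose(back, p, atol=1e-9)

    def test_point_at_infinity(self):
        m = np.eye(3)
        m[2] = [1.0, 0.0, 0.0]  # x = 0 line maps to infinity... use p=(0,y)
        h = reach.Homography(m + 1e-13 * np.eye(3))
        with pytest.raises(ProjectionError):
            reach.project(h, (0.0, 5.0))


class TestTrajectories:
    def test_identity_vertical(self):
        h = reach.Homography(np.eye(3))
        holder = reach.HolderGeometry(
            available_angles_deg=(89.9,), needle_length_mm=100.0
        )
        traj = reach.predict_tip_trajectories(h, holder, n_samples=20)
        pts = traj[89.9]["points"]
        assert np.abs(pts[:, 0] - pts[0, 0]).max() < 0.2  # near-vertical
        assert pts[-1, 1] > pts[0, 1]

    def test_five_angles_five_trajectories(self):
        h = reach.Homography(np.eye(3))
        traj = reach.predict_tip_trajectories(h, reach.HolderGeometry())
        assert len(traj) == 5

    def test_projected_lines_stay_straight(self):
        """Projective maps preserve straight lines."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            h = reach.Homography(_random_homography(rng))
            holder = reach.HolderGeometry(available_angles_deg=(40.0, 60.0))
            traj = reach.predict_tip_trajectories(h, holder, n_samples=50)
            for t in traj.values():
                pts = t["points"]
                d = pts[-1] - pts[0]
                d = d / np.linalg.norm(d)
                rel = pts - pts[0]
                residual = np.abs(rel @ np.array([-d[1], d[0]]))
                assert residual.max() < 1e-6 * np.abs(pts).max()

    def test_outside_flagging(self):
        h = reach.Homography(np.eye(3))
        holder = reach.HolderGeometry(
            available_angles_deg=(45.0,),
            mount_offset=reach.RigidTransform2D(translation=(1000.0, 1000.0)),
        )
        traj = reach.predict_tip_trajectories(
            h, holder, image_bounds=(0, 0, 100, 100)
        )
        assert traj[45.0]["outside"] is True
        assert 45.0 in traj  # flagged, not dropped


class TestInReach:
    def _target(self, cx, cy, s=10.0):
        return Annotation("target", (cx - s / 2, cy - s / 2, s, s))

    def test_trajectory_through_center(self):
        h = reach.Homography(np.eye(3))
        holder = reach.HolderGeometry(available_angles_deg=(45.0,),
                                      needle_length_mm=150.0)
        traj = reach.predict_tip_trajectories(h, holder, n_samples=500)
        d = 60.0 / np.sqrt(2)
        decision = reach.in_reach(self._target(d, d), traj, tolerance=1.0)
        assert decision.reachable
        assert decision.miss_distance < 0.2
        assert decision.best_angle_deg == 45.0
        assert decision.depth_mm == pytest.approx(60.0, abs=1.0)

    def test_unreachable_when_far(self):
        h = reach.Homography(np.eye(3))
        holder = reach.HolderGeometry(available_angles_deg=(45.0,),
                                      needle_length_mm=100.0)
        traj = reach.predict_tip_trajectories(h, holder)
        decision = reach.in_reach(self._target(-50.0, 50.0), traj, tolerance=2.0)
        assert not decision.reachable

    def test_best_angle_matches_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        h = reach.Homography(_random_homography(rng))
        holder = reach.HolderGeometry(needle_length_mm=120.0)
        traj = reach.predict_tip_trajectories(h, holder, n_samples=400)
        target = self._target(30.0, 25.0)
        decision = reach.in_reach(target, traj, tolerance=5.0)
        center = np.array([30.0, 25.0])
        best_angle, best_miss = None, np.inf
        for angle in holder.available_angles_deg:
            pts = traj[angle]["points"]
            miss = np.linalg.norm(pts - center, axis=1).min()
            if miss < best_miss:
                best_angle, best_miss = angle, miss
        assert decision.best_angle_deg == best_angle
        assert decision.miss_distance == pytest.approx(best_miss)

    def test_empty_trajectories_rejected(self):
        with pytest.raises(ValueError):
            reach.in_reach(self._target(0, 0), {}, 1.0)


class TestReprojectionRMSE:
    def test_exact_pairs_zero(self):
        rng = np.random.default_rng(7)
        h_true = _random_homography(rng)
        pairs = _pairs_from_h(h_true, 9, rng)
        h = reach.estimate_homography(pairs)
        assert reach.reprojection_rmse(h, pairs) < 1e-8

    def test_single_offset_point_gives_one_mm(self):
        """One of nine points off by 3 mm -> RMSE = sqrt(9/9) = 1 mm."""
        h = reach.Homography(np.eye(3))
        pairs = [
            reach.PointPair((float(i), float(j)), (float(i), float(j)))
            for i in range(3)
            for j in range(3)
        ]
        pairs[0] = reach.PointPair((0.0, 0.0), (3.0, 0.0))
        assert reach.reprojection_rmse(h, pairs) == pytest.approx(1.0)

    def test_calibration_evaluation_split(self):
        """Fit on 6 synthetic interventions, evaluate on 3: noiseless
        data reprojects to well under 0.01 mm."""
        rng = np.random.default_rng(8)
        h_true = _random_homography(rng)
        all_pairs = _pairs_from_h(h_true, 9, rng)
        h = reach.estimate_homography(all_pairs[:6])
        assert reach.reprojection_rmse(h, all_pairs[6:]) < 0.01

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            reach.reprojection_rmse(reach.Homography(np.eye(3)), [])


def test_pairs_csv_and_homography_json_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    pairs = _pairs_from_h(np.eye(3), 5, rng)
    reach.write_pairs_csv(pairs, tmp_path / "pairs.csv")
    back = reach.read_pairs_csv(tmp_path / "pairs.csv")
    np.testing.assert_allclose([p.world for p in back], [p.world for p in pairs])
    h = reach.Homography(_random_homography(rng))
    h.to_json(tmp_path / "h.json")
    h2 = reach.Homography.from_json(tmp_path / "h.json")
    np.testing.assert_allclose(h2.matrix, h.matrix)
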