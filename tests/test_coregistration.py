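"""AX = YB solver, tracker-frame mapping, and fiducial registration."""

import numpy as np
import pytest

from facenav.coregistration import (DegenerateMotionError, HandEyeCalibration,
                                    InsufficientPairsError, PairedPose,
                                    fiducial_register, pair_streams, solve,
                                    to_tracker)
from facenav.geometry import (RigidTransform, compose, invert,
                              random_transform, rotation_distance,
                              translation_distance)
from facenav.synthetic import ScenarioConfig, coregistration_session


@pytest.fixture
def noiseless_session(noiseless_cfg):
    return coregistration_session(noiseless_cfg, n_pairs=500)


class TestSolver:
    def test_noiseless_exact_recovery(self, noiseless_session):
        b = noiseless_session
        res = HandEyeCalibration(b.pairs).fit()
        assert rotation_distance(res.X, b.true_X) < 1e-6
        assert translation_distance(res.X, b.true_X) < 1e-6
        assert rotation_distance(res.Y, b.true_Y) < 1e-6
        assert translation_distance(res.Y, b.true_Y) < 1e-6

    def test_identity_factors(self, rng):
        pairs = []
        for _ in range(20):
            A = random_transform(rng, max_angle_deg=40.0, max_translation_mm=300.0)
            pairs.append(PairedPose(A=A, B=A))
        res = HandEyeCalibration(pairs, min_pairs=3).fit()
        assert rotation_distance(res.X, RigidTransform.identity()) < 1e-9
        assert np.linalg.norm(res.X.translation) < 1e-8
        assert rotation_distance(res.Y, RigidTransform.identity()) < 1e-9
        assert res.mean_trans_residual_mm < 1e-8

    def test_residuals_track_injected_noise(self):
        """Mean per-pair residual matches the closed-form expected norm of the
        injected gaussian noise (chi distribution, k=3) within 25%."""
        cfg = ScenarioConfig(seed=50, tracker_noise_mm=0.0, tracker_noise_deg=0.0,
                             camera_pose_noise_mm=0.5, camera_pose_noise_deg=0.2)
        b = coregistration_session(cfg, n_pairs=500)
        res = HandEyeCalibration(b.pairs).fit()
        expected_t = 0.5 * np.sqrt(8.0 / np.pi)   # E||N(0, 0.5^2 I_3)||
        expected_r = 0.2 * np.sqrt(2.0 / np.pi)   # E|N(0, 0.2^2)| rotation angle
        assert abs(res.mean_trans_residual_mm - expected_t) / expected_t < 0.25
        assert abs(res.mean_rot_residual_deg - expected_r) / expected_r < 0.25

    def test_recovery_improves_with_more_pairs(self):
        """X-recovery error strictly decreases in expectation N=10 -> 50 -> 500."""
        errs = {10: [], 50: [], 500: []}
        for rep in range(10):
            cfg = ScenarioConfig(seed=200 + rep,
                                 tracker_noise_mm=0.0, tracker_noise_deg=0.0,
                                 camera_pose_noise_mm=0.5, camera_pose_noise_deg=0.2)
            b = coregistration_session(cfg, n_pairs=500)
            for n in errs:
                res = HandEyeCalibration(b.pairs[:n], min_pairs=3).fit()
                errs[n].append(translation_distance(res.X, b.true_X)
                               + rotation_distance(res.X, b.true_X))
        assert np.mean(errs[50]) < np.mean(errs[10])
        assert np.mean(errs[500]) < np.mean(errs[50])

    def test_min_pairs_policy(self, noiseless_session):
        with pytest.raises(InsufficientPairsError, match="500"):
            HandEyeCalibration(noiseless_session.pairs[:499])
        res = HandEyeCalibration(noiseless_session.pairs[:10], min_pairs=10).fit()
        assert res.n_pairs == 10

    def test_degenerate_single_axis_motion_rejected(self, noiseless_cfg):
        b = coregistration_session(noiseless_cfg, n_pairs=50, single_axis=True)
        assert b.degenerate_motion_warning
        with pytest.raises(DegenerateMotionError, match="independent directions"):
            HandEyeCalibration(b.pairs, min_pairs=3).fit()

    def test_equivariance_prediction_invariance(self, noiseless_cfg, rng):
        """Re-expressing all tracker measurements in another frame changes X
        but leaves the per-pair predictions of B identical."""
        b = coregistration_session(noiseless_cfg, n_pairs=100)
        G = random_transform(rng, max_angle_deg=60.0, max_translation_mm=500.0)
        moved = [PairedPose(A=compose(G, p.A), B=p.B) for p in b.pairs]
        res0 = HandEyeCalibration(b.pairs, min_pairs=3).fit()
        res1 = HandEyeCalibration(moved, min_pairs=3).fit()
        for p, m in zip(b.pairs[:10], moved[:10]):
            B0 = res0.predict(p.A)
            B1 = res1.predict(m.A)
            assert rotation_distance(B0, B1) < 1e-6
            assert translation_distance(B0, B1) < 1e-6

    def test_residuals_stationary_across_session(self):
        """No drift: first- and last-quartile residual means agree within 2 SE."""
        cfg = ScenarioConfig(seed=60, tracker_noise_mm=0.0, tracker_noise_deg=0.0,
                             camera_pose_noise_mm=0.5, camera_pose_noise_deg=0.2)
        b = coregistration_session(cfg, n_pairs=500)
        res = HandEyeCalibration(b.pairs).fit()
        q = len(res.trans_residuals_mm) // 4
        first, last = res.trans_residuals_mm[:q], res.trans_residuals_mm[-q:]
        se = np.sqrt(first.var(ddof=1) / q + last.var(ddof=1) / q)
        assert abs(first.mean() - last.mean()) < 2.0 * se


def _results_with_X(X):
    from facenav.coregistration import CoregistrationResults
    return CoregistrationResults(
        X=X, Y=RigidTransform.identity(),
        rot_residuals_deg=np.zeros(1), trans_residuals_mm=np.zeros(1),
        n_pairs=1, n_dropped=0, condition_number=1.0,
        axis_singular_values=np.ones(3), refined=False)


class TestToTracker:
    def test_identity_X_passthrough(self, rng):
        res = _results_with_X(RigidTransform.identity())
        T = random_transform(rng, 30, 200)
        out = to_tracker(res, T)
        assert rotation_distance(out, T) < 1e-12
        assert translation_distance(out, T) < 1e-12

    def test_training_pair_consistency(self, noiseless_session):
        res = HandEyeCalibration(noiseless_session.pairs).fit()
        for p in noiseless_session.pairs[:10]:
            # to_tracker(B) . Y reproduces A within the pair's residual
            lhs = compose(res.to_tracker(p.B), res.Y)
            assert rotation_distance(lhs, p.A) < 1e-6
            assert translation_distance(lhs, p.A) < 1e-6

    def test_pure_translation_X(self):
        res = _results_with_X(RigidTransform(np.eye(3), [100.0, 0.0, 0.0]))
        out = res.to_tracker(RigidTransform.identity())
        np.testing.assert_allclose(out.translation, [-100.0, 0.0, 0.0], atol=1e-12)


class TestPairing:
    def test_nearest_neighbour_with_tolerance(self, rng):
        T = RigidTransform.identity()
        tracker = [(float(t), T) for t in range(10)]
        camera = [(t + 0.2, T) for t in range(9)] + [(55.0, T)]
        pairs, dropped = pair_streams(tracker, camera, tolerance_s=0.5)
        assert len(pairs) == 9
        assert dropped == 1
        assert all(abs(p.dt - 0.2) < 1e-12 for p in pairs)


class TestFiducialRegistration:
    FIDUCIALS = np.array([[0.0, 80.0, 20.0],     # nasion
                          [-70.0, 0.0, 0.0],     # right tragus
                          [70.0, 0.0, 0.0]])     # left tragus

    def test_identical_sets_give_identity(self):
        T, fre = fiducial_register(self.FIDUCIALS, self.FIDUCIALS)
        assert rotation_distance(T, RigidTransform.identity()) < 1e-9
        assert fre < 1e-9

    def test_known_rotation_recovered(self):
        from facenav.geometry import EulerPose, from_euler
        G = from_euler(EulerPose(10.0, -5.0, 30.0, 0.0, 25.0, 0.0))
        moved = G.apply(self.FIDUCIALS)
        T, fre = fiducial_register(moved, self.FIDUCIALS)
        assert rotation_distance(T, G) < 1e-9
        assert translation_distance(T, G) < 1e-9
        assert fre < 1e-9

    def test_perturbed_point_bounds_fre(self):
        moved = self.FIDUCIALS.copy()
        moved[0] += [0.0, 3.0, 0.0]
        T, fre = fiducial_register(moved, self.FIDUCIALS)
        # brute-force residual at the solution
        res = np.linalg.norm(T.apply(self.FIDUCIALS) - moved, axis=1)
        assert np.isclose(fre, np.sqrt(np.mean(res ** 2)), atol=1e-12)
        assert 0.0 < fre < 3.0

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateMotionError):
            fiducial_register(line, line)
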