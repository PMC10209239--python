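"""Landmark selection, anthropometric model validation, and PnP recovery."""

import numpy as np
import pytest

from facenav.geometry import (EulerPose, from_euler, rotation_distance,
                              translation_distance)
from facenav.headpose import (LANDMARK_INDEX_MAP, LANDMARK_NAMES,
                              AnthropometricModel, HeadPoseModel,
                              LandmarkObservation, LandmarkSelectionError,
                              ScaleUnidentifiableError, estimate_pose,
                              estimate_scale, select_landmarks)
from facenav.synthetic import ScenarioConfig, static_session


@pytest.fixture
def model():
    return AnthropometricModel.default()


@pytest.fixture
def full68(rng):
    return {i: rng.uniform(100, 900, size=2) for i in range(68)}


class TestSelectLandmarks:
    def test_complete_frame_yields_14_named_points(self, full68):
        obs = select_landmarks(full68)
        assert set(obs.points) == set(LANDMARK_NAMES)
        np.testing.assert_allclose(obs.points["chin"], full68[8])
        np.testing.assert_allclose(obs.points["eye_outer_r"], full68[36])
        np.testing.assert_allclose(obs.points["eye_outer_l"], full68[45])
        np.testing.assert_allclose(obs.points["mid_lower_lip"], full68[57])

    def test_missing_chin_named_in_error(self, full68):
        del full68[8]
        with pytest.raises(LandmarkSelectionError, match="chin"):
            select_landmarks(full68)

    def test_already_selected_array_rejected(self, rng):
        with pytest.raises(LandmarkSelectionError, match="already selected"):
            select_landmarks(rng.uniform(0, 100, size=(14, 2)))


class TestAnthropometricModel:
    def test_origin_landmark_is_at_origin(self, model):
        np.testing.assert_allclose(model.points[model.origin_landmark], 0.0)

    def test_bilateral_symmetry(self, model):
        from facenav.headpose import BILATERAL_PAIRS
        for r, l in BILATERAL_PAIRS:
            mirrored = model.points[l] * np.array([-1, 1, 1])
            assert np.linalg.norm(model.points[r] - mirrored) <= model.symmetry_tol_mm

    def test_not_coplanar(self, model):
        arr = model.as_array()
        assert np.linalg.matrix_rank(arr - arr.mean(axis=0), tol=1e-6) == 3

    def test_missing_structure_rejected(self, model):
        pts = dict(model.points)
        del pts["chin"]
        with pytest.raises(ValueError, match="chin"):
            AnthropometricModel(pts)

    def test_text_round_trip(self, model):
        back = AnthropometricModel.from_text(model.to_text())
        for n in LANDMARK_NAMES:
            np.testing.assert_allclose(back.points[n], model.points[n])


def _observe_at(cfg, pose, scale=1.0):
    from facenav.camera import project
    T = from_euler(pose)
    px = project(T.apply(scale * cfg.model.as_array()), cfg.intrinsics)
    return LandmarkObservation(
        timestamp=0.0, points={n: px[i] for i, n in enumerate(LANDMARK_NAMES)})


class TestPoseRecovery:
    @pytest.mark.parametrize("pose", [
        EulerPose(0, 0, 1000.0, 0, 0, 0),
        EulerPose(0, 0, 1000.0, 20.0, -10.0, 5.0),
        EulerPose(-80.0, 40.0, 1250.0, -15.0, 8.0, -12.0),
    ])
    def test_noiseless_recovery_is_exact(self, noiseless_cfg, pose):
        obs = _observe_at(noiseless_cfg, pose)
        T, fit = estimate_pose(obs, noiseless_cfg.model, noiseless_cfg.intrinsics)
        assert rotation_distance(T, from_euler(pose)) < 1e-4
        assert translation_distance(T, from_euler(pose)) < 1e-4
        assert fit.rms_px < 1e-6
        assert not fit.low_confidence

    def test_z_noise_anisotropy(self):
        """Pixel noise inflates depth (z) errors more than lateral x/y errors:
        depth is constrained only by the weak perspective scaling of the face."""
        cfg = ScenarioConfig(seed=21, pixel_noise_px=0.5)
        true_pose = EulerPose(0, 0, 1000.0, 0, 0, 0)
        hp = HeadPoseModel(cfg.model, cfg.intrinsics)
        rng = np.random.default_rng(99)
        from facenav.camera import project
        T = from_euler(true_pose)
        clean = project(T.apply(cfg.model.as_array()), cfg.intrinsics)
        errs = []
        for _ in range(200):
            px = clean + rng.normal(0, 0.5, clean.shape)
            obs = LandmarkObservation(
                timestamp=0.0,
                points={n: px[i] for i, n in enumerate(LANDMARK_NAMES)})
            fit = hp.fit(obs)
            errs.append(fit.transform.translation - T.translation)
        sd = np.std(errs, axis=0, ddof=1)
        assert sd[2] > sd[0]
        assert sd[2] > sd[1]

    def test_error_monotone_in_pixel_noise(self):
        """Mean pose error is non-decreasing across noise levels in expectation."""
        cfg = ScenarioConfig(seed=22)
        hp = HeadPoseModel(cfg.model, cfg.intrinsics)
        from facenav.camera import project
        T = from_euler(EulerPose(0, 0, 1000.0, 10.0, -5.0, 3.0))
        clean = project(T.apply(cfg.model.as_array()), cfg.intrinsics)
        rng = np.random.default_rng(5)
        means = []
        for sigma in (0.0, 0.25, 0.5, 1.0):
            errs = []
            for _ in range(100):
                px = clean + rng.normal(0, sigma, clean.shape) if sigma else clean
                obs = LandmarkObservation(
                    timestamp=0.0,
                    points={n: px[i] for i, n in enumerate(LANDMARK_NAMES)})
                errs.append(np.linalg.norm(hp.fit(obs).transform.translation
                                           - T.translation))
            means.append(np.mean(errs))
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))

    def test_confidence_weights_downweight_bad_landmark(self, noiseless_cfg):
        pose = EulerPose(0, 0, 1000.0, 5.0, 0, 0)
        obs = _observe_at(noiseless_cfg, pose)
        pts = {k: v.copy() for k, v in obs.points.items()}
        pts["chin"] = pts["chin"] + np.array([30.0, -20.0])
        corrupted = LandmarkObservation(0.0, pts)
        downweighted = LandmarkObservation(
            0.0, pts, confidence={n: (0.0 if n == "chin" else 1.0)
                                  for n in LANDMARK_NAMES})
        _, fit_bad = estimate_pose(corrupted, noiseless_cfg.model,
                                   noiseless_cfg.intrinsics)
        T_good, _ = estimate_pose(downweighted, noiseless_cfg.model,
                                  noiseless_cfg.intrinsics)
        err_bad = translation_distance(fit_bad.transform
                                       if hasattr(fit_bad, "transform") else fit_bad,
                                       from_euler(pose))
        err_good = translation_distance(T_good, from_euler(pose))
        assert err_good < err_bad


class TestScaleEstimation:
    def test_scaled_model_recovered(self, rng):
        cfg = ScenarioConfig(seed=31, pixel_noise_px=0.0, true_scale=1.10)
        bundle = static_session(cfg, distance_mm=1000.0)
        s = estimate_scale(bundle.observations[:5], cfg.model, cfg.intrinsics,
                           known_distance_mm=1000.0)
        assert abs(s - 1.10) < 1e-3

    def test_unit_scale_is_identity(self):
        cfg = ScenarioConfig(seed=32, pixel_noise_px=0.0, true_scale=1.0)
        bundle = static_session(cfg, distance_mm=1000.0)
        s = estimate_scale(bundle.observations[:3], cfg.model, cfg.intrinsics,
                           known_distance_mm=1000.0)
        assert abs(s - 1.0) < 1e-6

    def test_more_observations_reduce_error(self):
        """Averaging over 25 frames beats a single frame under pixel noise."""
        err1, err25 = [], []
        for seed in range(6):
            cfg = ScenarioConfig(seed=40 + seed, pixel_noise_px=0.5,
                                 true_scale=1.10)
            bundle = static_session(cfg, distance_mm=1000.0)
            err1.append(abs(estimate_scale(bundle.observations[:1], cfg.model,
                                           cfg.intrinsics, 1000.0) - 1.10))
            err25.append(abs(estimate_scale(bundle.observations[:25], cfg.model,
                                            cfg.intrinsics, 1000.0) - 1.10))
        assert np.mean(err25) < np.mean(err1)

    def test_missing_anchor_is_an_explicit_error(self, model):
        cfg = ScenarioConfig(seed=33, pixel_noise_px=0.0)
        bundle = static_session(cfg, distance_mm=1000.0)
        with pytest.raises(ScaleUnidentifiableError):
            estimate_scale(bundle.observations[:1], cfg.model, cfg.intrinsics)


class TestTracking:
    def test_static_noiseless_stream_is_constant(self, noiseless_cfg):
        bundle = static_session(noiseless_cfg, distance_mm=1000.0)
        hp = HeadPoseModel(noiseless_cfg.model, noiseless_cfg.intrinsics)
        stream = hp.track(bundle.observations[:10])
        assert np.all(stream.valid)
        assert np.allclose(stream.data.std(axis=0), 0.0, atol=1e-9)

    def test_corrupted_frame_flagged_neighbors_unaffected(self, noiseless_cfg):
        bundle = static_session(noiseless_cfg, distance_mm=1000.0)
        obs = bundle.observations[:7]
        pts = {k: v.copy() for k, v in obs[3].points.items()}
        pts["eye_outer_l"] = pts["eye_outer_l"] + np.array([50.0, 0.0])
        obs[3] = LandmarkObservation(obs[3].timestamp, pts)
        hp = HeadPoseModel(noiseless_cfg.model, noiseless_cfg.intrinsics,
                           residual_gate_px=5.0)
        stream = hp.track(obs)
        assert not stream.valid[3]
        assert stream.valid[2] and stream.valid[4]
        ref = stream.data[0]
        np.testing.assert_allclose(stream.data[2], ref, atol=1e-6)
        np.testing.assert_allclose(stream.data[4], ref, atol=1e-6)

    def test_warm_start_matches_cold_start_on_clean_data(self, noiseless_cfg):
        bundle = static_session(noiseless_cfg, distance_mm=1000.0)
        hp = HeadPoseModel(noiseless_cfg.model, noiseless_cfg.intrinsics)
        warm = hp.track(bundle.observations[:8], warm_start=True)
        cold = hp.track(bundle.observations[:8], warm_start=False)
        np.testing.assert_allclose(warm.data, cold.data, atol=1e-8)
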