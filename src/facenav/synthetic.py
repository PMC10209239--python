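"""Seeded scene simulator: cameras, faces and tracking hardware in software.

Generates every input the pipeline consumes — landmark observation
streams, paired camera/tracker pose streams, coil-revisit sessions and
checkerboard calibration views — with the ground truth attached, so every
downstream estimate can be checked against what generated it.

Emulated protocols (defaults):

* static session — a static frontal face at 100/125/150 cm from the
  camera, sampled every 2 s for 180 s (90 frames), isotropic gaussian
  pixel noise on each landmark;
* coregistration session — 500 paired poses of randomised head motion
  observed simultaneously by the tracker (A_i) and, through the true
  X, Y, by the camera (B_i = X.A_i.Y^-1), with independent noise on each
  stream;
* revisit session — 10 repositionings of a tracked coil onto a target,
  each draw gated by the 3 mm / 3 deg acceptance window before being
  "saved", mirroring the operator protocol;
* checkerboard views — board-point/pixel correspondences from random
  board poses fully inside the image, 1000 views as the operational
  preset (the solver needs only 3).

Noise models are declared, not inferred from hardware: isotropic gaussian
pixel noise on landmarks; gaussian translation noise plus small-angle
gaussian rotation noise about a uniformly random axis on tracker poses.

All randomness flows from one integer seed through named substreams
(`_rng`), so adding a new draw site never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .camera import CalibrationView, CameraIntrinsics, project
from .characterization import target_reached
from .coregistration import PairedPose
from .geometry import EulerPose, RigidTransform, compose, from_euler, invert
from .headpose import LANDMARK_NAMES, AnthropometricModel, LandmarkObservation

#: fixed substream labels -> offsets mixed into the seed sequence
_STREAMS = {
    "landmarks": 1,
    "trajectory": 2,
    "tracker": 3,
    "operator": 4,
    "board": 5,
    "corners": 6,
}

#: camera-face distance presets (mm) of the static protocol
DISTANCE_PRESETS_MM = (1000.0, 1250.0, 1500.0)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def default_intrinsics() -> CameraIntrinsics:
    """A 1080p consumer webcam (c920-class: 1920x1080, ~70 deg horizontal
    field of view -> f ~ 1360 px), no lens distortion."""
    return CameraIntrinsics(fx=1360.0, fy=1360.0, cx=960.0, cy=540.0,
                            image_size=(1920, 1080))


def _random_small_rotation(rng: np.random.Generator, sigma_deg: float
                           ) -> np.ndarray:
    """Rotation vector (radians): gaussian angle about a uniform axis."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return axis * np.radians(rng.normal(0.0, sigma_deg))


def perturb_transform(T: RigidTransform, rng: np.random.Generator,
                      sigma_t_mm: float, sigma_r_deg: float) -> RigidTransform:
    """Apply independent gaussian translation and small-angle rotation noise.

    The two components are perturbed separately — the rotation by a
    small-angle rotation about a uniformly random axis, the translation by
    an additive isotropic gaussian — so the rotation noise does not leak
    into the translation through the lever arm of the pose.
    """
    if sigma_t_mm == 0.0 and sigma_r_deg == 0.0:
        return T
    dR = RigidTransform.from_rotvec(_random_small_rotation(rng, sigma_r_deg),
                                    np.zeros(3))
    noisy = compose(dR, T)
    return RigidTransform(noisy.rotation,
                          T.translation + rng.normal(0.0, sigma_t_mm, size=3),
                          _skip_check=True)


@dataclass
class ScenarioConfig:
    """Everything that defines a simulated session, including its seed."""

    seed: int = 0
    intrinsics: CameraIntrinsics = field(default_factory=default_intrinsics)
    model: AnthropometricModel = field(default_factory=AnthropometricModel.default)
    true_scale: float = 1.0
    true_X: Optional[RigidTransform] = None   # T_camera^tracker
    true_Y: Optional[RigidTransform] = None   # T_headpose^marker
    head_pose: Optional[EulerPose] = None     # static trajectory
    pixel_noise_px: float = 0.3
    tracker_noise_mm: float = 0.1
    tracker_noise_deg: float = 0.05
    camera_pose_noise_mm: float = 0.1
    camera_pose_noise_deg: float = 0.05
    frame_rate_hz: float = 0.5                # one sample every 2 s
    duration_s: float = 180.0

    def __post_init__(self):
        for name in ("pixel_noise_px", "tracker_noise_mm", "tracker_noise_deg",
                     "camera_pose_noise_mm", "camera_pose_noise_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolved_X(self) -> RigidTransform:
        if self.true_X is not None:
            return self.true_X
        # tracker mounted above and to the side of the camera, tilted 30 deg
        return RigidTransform.from_rotvec(np.radians([0.0, 30.0, 0.0]),
                                          [400.0, -300.0, 150.0])

    def resolved_Y(self) -> RigidTransform:
        if self.true_Y is not None:
            return self.true_Y
        # head marker strapped above the forehead
        return RigidTransform.from_rotvec(np.radians([10.0, 0.0, 5.0]),
                                          [0.0, -150.0, 40.0])


@dataclass
class GroundTruthBundle:
    """Simulator output: generated streams plus the truth that made them."""

    config: ScenarioConfig
    observations: list[LandmarkObservation] = field(default_factory=list)
    true_camera_poses: list[RigidTransform] = field(default_factory=list)
    true_tracker_poses: list[RigidTransform] = field(default_factory=list)
    pairs: list[PairedPose] = field(default_factory=list)
    visits: list[EulerPose] = field(default_factory=list)
    views: list[CalibrationView] = field(default_factory=list)
    pixel_noise_draws: Optional[np.ndarray] = None
    degenerate_motion_warning: bool = False

    @property
    def true_X(self) -> RigidTransform:
        return self.config.resolved_X()

    @property
    def true_Y(self) -> RigidTransform:
        return self.config.resolved_Y()


def _observe(T_cam_head: RigidTransform, cfg: ScenarioConfig,
             noise_px: np.ndarray, timestamp: float) -> LandmarkObservation:
    pts3d = cfg.true_scale * cfg.model.as_array()
    cam = T_cam_head.apply(pts3d)
    px = project(cam, cfg.intrinsics) + noise_px
    return LandmarkObservation(
        timestamp=timestamp,
        points={n: px[i] for i, n in enumerate(LANDMARK_NAMES)})


def static_session(cfg: ScenarioConfig,
                   distance_mm: float = DISTANCE_PRESETS_MM[0]
                   ) -> GroundTruthBundle:
    """Static frontal face at ``distance_mm``; 90 frames by default."""
    if cfg.head_pose is not None:
        pose = cfg.head_pose
    else:
        pose = EulerPose(0.0, 0.0, distance_mm, 0.0, 0.0, 0.0)
    T = from_euler(pose)
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    rng = _rng(cfg.seed, "landmarks")
    noise = rng.normal(0.0, cfg.pixel_noise_px, size=(n_frames, len(LANDMARK_NAMES), 2)) \
        if cfg.pixel_noise_px > 0 else np.zeros((n_frames, len(LANDMARK_NAMES), 2))
    bundle = GroundTruthBundle(config=cfg, pixel_noise_draws=noise)
    for i in range(n_frames):
        ts = i / cfg.frame_rate_hz
        bundle.observations.append(_observe(T, cfg, noise[i], ts))
        bundle.true_camera_poses.append(T)
    return bundle


def _random_head_motion(rng: np.random.Generator, n: int,
                        single_axis: bool = False) -> list[RigidTransform]:
    """Randomised head orientations/positions as seen by the tracker."""
    out = []
    fixed_axis = np.array([0.0, 0.0, 1.0])
    for _ in range(n):
        if single_axis:
            axis = fixed_axis
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(-40.0, 40.0))
        t = np.array([rng.uniform(-100, 100), rng.uniform(-100, 100),
                      rng.uniform(400, 800)])
        out.append(RigidTransform.from_rotvec(axis * angle, t))
    return out


def coregistration_session(cfg: ScenarioConfig, n_pairs: int = 500,
                           single_axis: bool = False) -> GroundTruthBundle:
    """Paired (tracker, camera) poses through the true X, Y.

    B_i = X . A_i . Y^-1 exactly, then independent noise on each stream:
    pixel-derived noise is abstracted as pose noise of the configured
    tracker magnitudes on B, tracker noise on A.  A deliberately
    degenerate ``single_axis`` trajectory trips the generator's own
    warning, consumed by tests.
    """
    X, Y = cfg.resolved_X(), cfg.resolved_Y()
    traj = _random_head_motion(_rng(cfg.seed, "trajectory"), n_pairs,
                               single_axis=single_axis)
    noise_rng = _rng(cfg.seed, "tracker")
    bundle = GroundTruthBundle(config=cfg)
    bundle.degenerate_motion_warning = single_axis
    Yinv = invert(Y)
    for i, A in enumerate(traj):
        B = compose(compose(X, A), Yinv)
        A_meas = perturb_transform(A, noise_rng, cfg.tracker_noise_mm,
                                   cfg.tracker_noise_deg)
        B_meas = perturb_transform(B, noise_rng, cfg.camera_pose_noise_mm,
                                   cfg.camera_pose_noise_deg)
        ts = i / max(cfg.frame_rate_hz, 1e-9)
        bundle.pairs.append(PairedPose(A=A_meas, B=B_meas, timestamp=ts))
        bundle.true_tracker_poses.append(A)
        bundle.true_camera_poses.append(B)
    return bundle


def revisit_session(cfg: ScenarioConfig, target: EulerPose, n_visits: int = 10,
                    operator_sigma_mm: float = 1.2,
                    operator_sigma_deg: float = 1.0,
                    tol_mm: float = 3.0, tol_deg: float = 3.0,
                    max_attempts: int = 10000) -> GroundTruthBundle:
    """Coil repositionings onto ``target``, gated by the acceptance window.

    Each visit is drawn around the target with the operator's aiming noise
    and only "saved" once it satisfies the 3 mm / 3 deg window, exactly as
    the operator protocol saves coordinates.
    """
    if operator_sigma_mm < 0 or operator_sigma_deg < 0:
        raise ValueError("operator noise must be >= 0")
    rng = _rng(cfg.seed, "operator")
    bundle = GroundTruthBundle(config=cfg)
    for i in range(n_visits):
        for _ in range(max_attempts):
            dt = rng.normal(0.0, operator_sigma_mm, size=3)
            da = rng.normal(0.0, operator_sigma_deg, size=3)
            visit = EulerPose(target.x + dt[0], target.y + dt[1],
                              target.z + dt[2], target.yaw + da[0],
                              target.pitch + da[1], target.roll + da[2],
                              timestamp=float(i))
            reached, _ = target_reached(visit, target, tol_mm, tol_deg)
            if reached:
                bundle.visits.append(visit)
                break
        else:
            raise RuntimeError("operator never reached the target window")
    return bundle


def checkerboard_views(cfg: ScenarioConfig, n_views: int = 1000,
                       rows: int = 7, cols: int = 9, square_mm: float = 25.0,
                       corner_noise_px: float = 0.0,
                       max_retries: int = 200) -> GroundTruthBundle:
    """Board-point/pixel correspondences from random in-frame board poses."""
    if cfg.intrinsics.image_size is None:
        raise ValueError("checkerboard simulation needs a declared image size")
    w, h = cfg.intrinsics.image_size
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    board = np.column_stack([jj.ravel() * square_mm, ii.ravel() * square_mm,
                             np.zeros(rows * cols)])
    board = board - board.mean(axis=0)  # board frame centred on the pattern
    pose_rng = _rng(cfg.seed, "board")
    noise_rng = _rng(cfg.seed, "corners")
    bundle = GroundTruthBundle(config=cfg)
    for _ in range(n_views):
        for attempt in range(max_retries):
            rv = np.radians([pose_rng.uniform(-35, 35),
                             pose_rng.uniform(-35, 35),
                             pose_rng.uniform(-180, 180)])
            t = np.array([pose_rng.uniform(-80, 80),
                          pose_rng.uniform(-60, 60),
                          pose_rng.uniform(500, 900)])
            T = RigidTransform.from_rotvec(rv, t)
            cam = T.apply(board)
            if np.any(cam[:, 2] <= 10.0):
                continue
            px = project(cam, cfg.intrinsics)
            if np.all((px[:, 0] >= 0) & (px[:, 0] < w)
                      & (px[:, 1] >= 0) & (px[:, 1] < h)):
                if corner_noise_px > 0:
                    px = px + noise_rng.normal(0.0, corner_noise_px, size=px.shape)
                bundle.views.append(CalibrationView(board.copy(), px))
                bundle.true_camera_poses.append(T)
                break
        else:
            raise RuntimeError("could not place the board inside the frame")
    return bundle
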