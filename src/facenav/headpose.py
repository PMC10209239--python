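"""Head-pose estimation from 2D facial landmarks and a 3D face model.

The head pose is recovered as a perspective-n-point (PnP) problem: 14
named facial structures — the inner/outer corners of both eyebrows and
both eyes, the bottom nostril corners, the two labial commissures, the
middle lower lip and the chin — are located in the image by any 68-point
landmark detector, matched to a fixed anthropometric 3D model of the same
structures, and the rigid transform mapping the (uniformly scaled) model
into the camera frame is found by DLT initialisation followed by
Levenberg-Marquardt minimisation of the re-projection error.

The anthropometric scale of the subject's face relative to the model is
unidentifiable per-frame (it trades off against z-translation), so it is
estimated once per session from a batch of observations and frozen.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .camera import CameraIntrinsics, pixels_to_normalized, project
from .filters import PoseStream
from .geometry import RigidTransform, to_euler

#: The 14 facial structures used for the 3D fit, with their indices in the
#: standard 68-point (iBUG 300-W) landmark numbering.  Left/right are
#: anatomical (the subject's own left/right).
LANDMARK_INDEX_MAP: dict[str, int] = {
    "eyebrow_outer_r": 17,
    "eyebrow_inner_r": 21,
    "eyebrow_inner_l": 22,
    "eyebrow_outer_l": 26,
    "eye_outer_r": 36,
    "eye_inner_r": 39,
    "eye_inner_l": 42,
    "eye_outer_l": 45,
    "nostril_r": 31,
    "nostril_l": 35,
    "mouth_corner_r": 48,
    "mouth_corner_l": 54,
    "mid_lower_lip": 57,
    "chin": 8,
}

LANDMARK_NAMES: tuple[str, ...] = tuple(LANDMARK_INDEX_MAP)

#: Bilateral pairs, mirror-symmetric about the sagittal (x = 0) plane.
BILATERAL_PAIRS = (
    ("eyebrow_outer_r", "eyebrow_outer_l"),
    ("eyebrow_inner_r", "eyebrow_inner_l"),
    ("eye_outer_r", "eye_outer_l"),
    ("eye_inner_r", "eye_inner_l"),
    ("nostril_r", "nostril_l"),
    ("mouth_corner_r", "mouth_corner_l"),
)

# Default anthropometric coordinates (mm), head frame: x to the subject's
# left (image right for a frontal view), y down, z into the head (so
# protruding features have negative z).  Lateral/vertical placements and
# depth relief are synthetic averages in line with published facial
# anthropometry norms (inter-endocanthion ~32 mm, nasal base ~18 mm and
# lower lip ~16 mm anterior to the eye-corner plane, exocanthion ~12 mm
# posterior).  Any user model can be substituted via file; the simulator
# uses this same model as ground truth, so the pipeline's correctness is
# independent of the default's anthropometric fidelity.
_DEFAULT_POINTS: dict[str, tuple[float, float, float]] = {
    "eyebrow_outer_r": (-52.0, -18.0, 8.0),
    "eyebrow_inner_r": (-18.0, -22.0, -5.0),
    "eyebrow_inner_l": (18.0, -22.0, -5.0),
    "eyebrow_outer_l": (52.0, -18.0, 8.0),
    "eye_outer_r": (-45.0, 3.0, 12.0),
    "eye_inner_r": (-16.0, 0.0, 0.0),
    "eye_inner_l": (16.0, 0.0, 0.0),
    "eye_outer_l": (45.0, 3.0, 12.0),
    "nostril_r": (-17.0, 40.0, -18.0),
    "nostril_l": (17.0, 40.0, -18.0),
    "mouth_corner_r": (-28.0, 68.0, -8.0),
    "mouth_corner_l": (28.0, 68.0, -8.0),
    "mid_lower_lip": (0.0, 82.0, -16.0),
    "chin": (0.0, 118.0, -12.0),
}


class LandmarkSelectionError(ValueError):
    """Missing or malformed landmark input."""


class PoseRejectedError(RuntimeError):
    """The PnP solution is physically inadmissible (head behind camera)."""


class DegenerateObservationError(ValueError):
    """Observation geometry cannot constrain the pose (collinear landmarks)."""


@dataclass
class AnthropometricModel:
    """Named 3D coordinates (mm) of the 14 facial structures in the head frame.

    The model is re-centred on construction so that ``origin_landmark``
    sits at the head-frame origin; the reported head position is therefore
    that landmark's location in camera coordinates.
    """

    points: dict[str, np.ndarray]
    origin_landmark: str = "chin"
    symmetry_tol_mm: float = 5.0

    def __post_init__(self):
        names = set(self.points)
        if names != set(LANDMARK_NAMES):
            missing = sorted(set(LANDMARK_NAMES) - names)
            extra = sorted(names - set(LANDMARK_NAMES))
            raise ValueError(f"model must name exactly the 14 structures; "
                             f"missing={missing} extra={extra}")
        if self.origin_landmark not in self.points:
            raise ValueError(f"unknown origin landmark {self.origin_landmark!r}")
        pts = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        origin = pts[self.origin_landmark].copy()
        self.points = {k: v - origin for k, v in pts.items()}
        for r, l in BILATERAL_PAIRS:
            mirrored = self.points[l] * np.array([-1.0, 1.0, 1.0])
            if np.linalg.norm(self.points[r] - mirrored) > self.symmetry_tol_mm:
                raise ValueError(f"bilateral pair ({r}, {l}) violates sagittal "
                                 f"symmetry beyond {self.symmetry_tol_mm} mm")
        arr = self.as_array()
        centered = arr - arr.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-6) < 3:
            raise ValueError("model points are coplanar; 6-DoF pose is unobservable")

    @classmethod
    def default(cls, origin_landmark: str = "chin") -> "AnthropometricModel":
        return cls({k: np.array(v) for k, v in _DEFAULT_POINTS.items()},
                   origin_landmark=origin_landmark)

    def as_array(self, names: Sequence[str] = LANDMARK_NAMES) -> np.ndarray:
        return np.array([self.points[n] for n in names])

    # -- plain-text table (name x y z), one row per landmark ----------
    def to_text(self) -> str:
        lines = [f"# anthropometric face model, origin={self.origin_landmark}, mm",
                 "# name x y z"]
        for n in LANDMARK_NAMES:
            x, y, z = self.points[n]
            lines.append(f"{n} {x:.17g} {y:.17g} {z:.17g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "AnthropometricModel":
        origin = "chin"
        pts = {}
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("#"):
                if "origin=" in line:
                    origin = line.split("origin=")[1].split(",")[0].strip()
                continue
            if not line:
                continue
            name, x, y, z = line.split()
            pts[name] = np.array([float(x), float(y), float(z)])
        return cls(pts, origin_landmark=origin)


@dataclass
class LandmarkObservation:
    """One frame of 2D landmark pixel coordinates for the 14 structures."""

    timestamp: float
    points: dict[str, np.ndarray]
    confidence: Optional[dict[str, float]] = None

    def __post_init__(self):
        if set(self.points) != set(LANDMARK_NAMES):
            missing = sorted(set(LANDMARK_NAMES) - set(self.points))
            raise LandmarkSelectionError(
                f"observation must contain the 14 structures; missing={missing}")
        self.points = {k: np.asarray(v, dtype=float).reshape(2)
                       for k, v in self.points.items()}
        for k, v in self.points.items():
            if not np.all(np.isfinite(v)):
                raise LandmarkSelectionError(f"non-finite coordinates for {k}")
        if self.confidence is not None:
            for k, c in self.confidence.items():
                if not 0.0 <= c <= 1.0:
                    raise LandmarkSelectionError(f"confidence for {k} outside [0,1]")

    def as_array(self, names: Sequence[str] = LANDMARK_NAMES) -> np.ndarray:
        return np.array([self.points[n] for n in names])

    def weights(self, names: Sequence[str] = LANDMARK_NAMES) -> np.ndarray:
        if self.confidence is None:
            return np.ones(len(names))
        return np.array([self.confidence.get(n, 1.0) for n in names])


def select_landmarks(full: dict[int, np.ndarray] | np.ndarray,
                     timestamp: float = 0.0,
                     confidence: Optional[dict[int, float]] = None
                     ) -> LandmarkObservation:
    """Reduce a 68-point detector frame to the 14 structures used for the fit.

    ``full`` is either a dict of iBUG index -> (u, v) or a 68x2 array.
    A 14-point input (an already-selected set) is rejected rather than
    passed through, so accidental double selection fails loudly.
    """
    if isinstance(full, np.ndarray):
        if full.shape == (14, 2):
            raise LandmarkSelectionError(
                "input looks already selected (14 points); expected the 68-point set")
        if full.shape != (68, 2):
            raise LandmarkSelectionError(f"expected 68x2 array, got {full.shape}")
        full = {i: full[i] for i in range(68)}
    elif len(full) == 14 and set(full) == set(LANDMARK_INDEX_MAP.values()):
        pass  # exactly the needed indices is acceptable from a sparse detector
    missing = [f"{name} (index {idx})" for name, idx in LANDMARK_INDEX_MAP.items()
               if idx not in full]
    if missing:
        raise LandmarkSelectionError(f"missing landmark indices: {', '.join(missing)}")
    pts = {name: np.asarray(full[idx], dtype=float)
           for name, idx in LANDMARK_INDEX_MAP.items()}
    conf = None
    if confidence is not None:
        conf = {name: float(confidence.get(idx, 1.0))
                for name, idx in LANDMARK_INDEX_MAP.items()}
    return LandmarkObservation(timestamp=timestamp, points=pts, confidence=conf)


# ---------------------------------------------------------------------------
# PnP solver
# ---------------------------------------------------------------------------

@dataclass
class HeadPoseFit:
    """Result of a single-frame PnP fit."""

    transform: RigidTransform
    residuals_px: dict[str, float]
    rms_px: float
    low_confidence: bool
    n_iterations: int

    def summary(self) -> str:
        e = to_euler(self.transform)
        lines = [
            "Head pose (camera frame)",
            f"t = ({e.x:.3f}, {e.y:.3f}, {e.z:.3f}) mm   "
            f"ypr = ({e.yaw:.3f}, {e.pitch:.3f}, {e.roll:.3f}) deg",
            f"re-projection RMS = {self.rms_px:.4g} px"
            + ("   [LOW CONFIDENCE]" if self.low_confidence else ""),
        ]
        return "\n".join(lines)


def _dlt_pose(model_pts: np.ndarray, norm_pts: np.ndarray) -> RigidTransform:
    """Direct linear transform initialisation on >= 6 non-coplanar points."""
    n = len(model_pts)
    A = np.zeros((2 * n, 12))
    for i, ((X, Y, Z), (x, y)) in enumerate(zip(model_pts, norm_pts)):
        A[2 * i] = [X, Y, Z, 1, 0, 0, 0, 0, -x * X, -x * Y, -x * Z, -x]
        A[2 * i + 1] = [0, 0, 0, 0, X, Y, Z, 1, -y * X, -y * Y, -y * Z, -y]
    _, _, vt = np.linalg.svd(A)
    P = vt[-1].reshape(3, 4)
    # the homogeneous solution has a sign ambiguity; pick the sign that
    # puts the face in front of the camera (cheirality)
    best = None
    for eps in (1.0, -1.0):
        M = eps * P[:, :3]
        u, s, vtr = np.linalg.svd(M)
        d = np.sign(np.linalg.det(u @ vtr))
        R = u @ np.diag([1.0, 1.0, d]) @ vtr
        t = eps * P[:, 3] / s.mean()
        z_mean = (model_pts @ R.T + t)[:, 2].mean()
        if best is None or z_mean > best[0]:
            best = (z_mean, R, t)
    _, R, t = best
    return RigidTransform(R, t, _skip_check=True)


class HeadPoseModel:
    """PnP model binding an anthropometric model to camera intrinsics.

    Parameters
    ----------
    model : AnthropometricModel
    intrinsics : CameraIntrinsics
    scale : float
        Uniform model scale for this subject (estimated once per session
        with `estimate_scale` and frozen).
    residual_gate_px : float
        Fits with re-projection RMS above this are flagged low-confidence.
    """

    def __init__(self, model: AnthropometricModel, intrinsics: CameraIntrinsics,
                 scale: float = 1.0, residual_gate_px: float = 10.0):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.model = model
        self.intrinsics = intrinsics
        self.scale = float(scale)
        self.residual_gate_px = float(residual_gate_px)
        self._model_arr = model.as_array()

    def _residuals(self, params: np.ndarray, obs_px: np.ndarray,
                   weights: np.ndarray) -> np.ndarray:
        rv, t = params[:3], params[3:]
        R = Rotation.from_rotvec(rv).as_matrix()
        cam = (self.scale * self._model_arr) @ R.T + t
        if np.any(cam[:, 2] <= 0):
            # push the optimizer away from behind-camera configurations
            return np.full(2 * len(obs_px), 1e6)
        pred = project(cam, self.intrinsics)
        return (np.sqrt(weights)[:, None] * (pred - obs_px)).ravel()

    def fit(self, obs: LandmarkObservation,
            warm_start: Optional[RigidTransform] = None) -> HeadPoseFit:
        obs_px = obs.as_array()
        weights = obs.weights()
        if warm_start is None:
            norm = pixels_to_normalized(obs_px, self.intrinsics)
            init = _dlt_pose(self.scale * self._model_arr, norm)
        else:
            init = warm_start
        p0 = np.concatenate([Rotation.from_matrix(init.rotation).as_rotvec(),
                             init.translation])
        sol = least_squares(self._residuals, p0, args=(obs_px, weights),
                            method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                            max_nfev=500)
        T = RigidTransform.from_rotvec(sol.x[:3], sol.x[3:])
        cam = (self.scale * self._model_arr) @ T.rotation.T + T.translation
        if np.any(cam[:, 2] <= 0):
            raise PoseRejectedError(
                "solution places the head at or behind the camera plane "
                f"(min z = {cam[:, 2].min():.1f} mm)")
        pred = project(cam, self.intrinsics)
        per = np.linalg.norm(pred - obs_px, axis=1)
        rms = float(np.sqrt(np.mean(per ** 2)))
        return HeadPoseFit(
            transform=T,
            residuals_px={n: float(r) for n, r in zip(LANDMARK_NAMES, per)},
            rms_px=rms,
            low_confidence=rms > self.residual_gate_px,
            n_iterations=int(sol.nfev),
        )

    def track(self, observations: Iterable[LandmarkObservation],
              warm_start: bool = True, rate_hz: Optional[float] = None
              ) -> PoseStream:
        """Per-frame pose estimation over a temporally ordered stream.

        Frames failing the residual gate (or rejected outright) are marked
        invalid; they are never interpolated.
        """
        poses = []
        prev: Optional[RigidTransform] = None
        for obs in observations:
            try:
                fit = self.fit(obs, warm_start=prev if warm_start else None)
            except (PoseRejectedError, np.linalg.LinAlgError):
                ep = to_euler(RigidTransform.identity(), timestamp=obs.timestamp)
                ep.valid = False
                poses.append(ep)
                prev = None
                continue
            ep = to_euler(fit.transform, timestamp=obs.timestamp)
            ep.valid = not fit.low_confidence
            poses.append(ep)
            prev = fit.transform if not fit.low_confidence else None
        return PoseStream.from_poses(poses, rate_hz=rate_hz,
                                     provenance="headpose-pnp")


def estimate_pose(obs: LandmarkObservation, model: AnthropometricModel,
                  k: CameraIntrinsics, scale: float = 1.0,
                  **kw) -> tuple[RigidTransform, HeadPoseFit]:
    """Single-frame PnP fit; returns (transform, fit report)."""
    fit = HeadPoseModel(model, k, scale=scale, **kw).fit(obs)
    return fit.transform, fit


class ScaleUnidentifiableError(ValueError):
    """Monocular scale cannot be estimated without a metric anchor."""


def estimate_scale(observations: Sequence[LandmarkObservation],
                   model: AnthropometricModel, k: CameraIntrinsics,
                   known_distance_mm: Optional[float] = None) -> float:
    """Closed-form session scale from a static acquisition.

    A uniform scale of the model about the camera origin is exactly
    invisible to perspective projection (scaling all camera-frame points
    by s leaves every pixel unchanged), so the scale cannot come from the
    re-projection error alone: it needs one metric anchor.  The protocol
    provides it — the camera-face distance of the static acquisition is
    known (100/125/150 cm presets).  The pose is fitted at scale 1 for
    each observation; the fitted head depth then scales inversely with the
    true subject scale, so

        scale = known_distance_mm / mean(fitted z)

    averaged over the observations.  Frozen thereafter for the session.
    """
    if len(observations) < 1:
        raise ValueError("need at least one observation")
    if known_distance_mm is None:
        raise ScaleUnidentifiableError(
            "the session scale needs a metric anchor: pass known_distance_mm "
            "(the protocol's camera-face distance)")
    if known_distance_mm <= 0:
        raise ValueError("known_distance_mm must be positive")
    for obs in observations:
        pts = obs.as_array()
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise DegenerateObservationError(
                "landmarks are collinear in the image; pose is unobservable")
    hp = HeadPoseModel(model, k, scale=1.0)
    depths = [hp.fit(obs).transform.translation[2] for obs in observations]
    return float(known_distance_mm / np.mean(depths))


def track(observations: Iterable[LandmarkObservation], model: AnthropometricModel,
          k: CameraIntrinsics, scale: float = 1.0, **kw) -> PoseStream:
    """Functional wrapper over `HeadPoseModel.track`."""
    return HeadPoseModel(model, k, scale=scale).track(observations, **kw)
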