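"""Camera-tracker coregistration: the robot-world/hand-eye AX = YB problem.

The markerless camera and the secondary tracking device observe the same
head simultaneously: the tracker measures the pose A_i = T_tracker^marker
of a rigid marker attached to the head, the camera measures the head pose
B_i = T_camera^headpose.  Two constant transforms link the streams —
X = T_camera^tracker between the device frames and Y = T_headpose^marker
between the two head-attached frames — through the identity

    X . A_i = B_i . Y        for every paired measurement i.

`HandEyeCalibration` solves for X and Y by least squares: the rotation
constraints vec(R_X R_Ai - R_Bi R_Y) = 0 are stacked into one linear
system via Kronecker products and solved by SVD, the raw factors are
projected onto the rotation group, translations follow from the induced
linear system, and an optional Levenberg-Marquardt pass refines all 12
parameters jointly.  On noise-free, non-degenerate motion the estimate is
exact to numerical round-off.

By default the solver requires at least 500 paired poses — the session
size used operationally — although 3 non-degenerate pairs are the
mathematical minimum; the policy is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import (RigidTransform, compose, invert, rotation_distance,
                       translation_distance)

#: Operational default for the number of paired poses per session.
DEFAULT_MIN_PAIRS = 500

#: Rotations with less than this angle carry no usable axis information.
_MIN_AXIS_ANGLE_DEG = 0.5


class DegenerateMotionError(ValueError):
    """Head motion does not span enough rotation axes to solve AX = YB."""


class InsufficientPairsError(ValueError):
    """Fewer paired poses than the configured session minimum."""


@dataclass
class PairedPose:
    """Simultaneous (tracker, camera) measurement of the same head pose.

    A = T_tracker^marker from the tracking device, B = T_camera^headpose
    from the markerless estimator.  ``dt`` records the timestamp offset
    between the two sources after pairing.
    """

    A: RigidTransform
    B: RigidTransform
    timestamp: float = 0.0
    dt: float = 0.0


@dataclass
class CoregistrationResults:
    """Estimated X, Y with per-pair residual diagnostics.

    ``rot_residuals_deg[i]`` / ``trans_residuals_mm[i]`` are the geodesic
    rotation angle and translation norm between X.A_i and B_i.Y.
    """

    X: RigidTransform
    Y: RigidTransform
    rot_residuals_deg: np.ndarray
    trans_residuals_mm: np.ndarray
    n_pairs: int
    n_dropped: int
    condition_number: float
    axis_singular_values: np.ndarray
    refined: bool

    @property
    def mean_rot_residual_deg(self) -> float:
        return float(self.rot_residuals_deg.mean())

    @property
    def mean_trans_residual_mm(self) -> float:
        return float(self.trans_residuals_mm.mean())

    def predict(self, A: RigidTransform) -> RigidTransform:
        """Predicted camera-side measurement B for a tracker measurement A:
        B = X . A . Y^-1."""
        return compose(compose(self.X, A), invert(self.Y))

    def to_tracker(self, b: RigidTransform) -> RigidTransform:
        """Map a camera-frame head pose into the tracker frame:
        T_tracker^headpose = X^-1 . B."""
        return compose(invert(self.X), b)

    def summary(self) -> str:
        lines = [
            "Camera-tracker coregistration (AX = YB least squares)",
            "=" * 56,
            f"pairs used: {self.n_pairs}   dropped in pairing: {self.n_dropped}",
            f"refinement: {'LM' if self.refined else 'linear only'}   "
            f"condition number: {self.condition_number:.3g}",
            "rotation-axis spread (singular values): "
            + " ".join(f"{s:.3f}" for s in self.axis_singular_values),
            f"residuals: rotation mean {self.mean_rot_residual_deg:.4g} deg "
            f"(max {self.rot_residuals_deg.max():.4g}), "
            f"translation mean {self.mean_trans_residual_mm:.4g} mm "
            f"(max {self.trans_residuals_mm.max():.4g})",
            "X (camera <- tracker):",
            np.array_str(self.X.as_matrix(), precision=6),
            "Y (headpose <- marker):",
            np.array_str(self.Y.as_matrix(), precision=6),
        ]
        return "\n".join(lines)


def _vec(M: np.ndarray) -> np.ndarray:
    return M.reshape(9, order="F")


def _unvec(v: np.ndarray) -> np.ndarray:
    return v.reshape(3, 3, order="F")


def _project_so3(M: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(M)
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return R


def _axis_spread(pairs: Sequence[PairedPose]) -> np.ndarray:
    """Singular values (normalised by sqrt(n)) of the stacked unit rotation
    axes of the tracker measurements A_i."""
    axes = []
    for p in pairs:
        rv = p.A.rotvec()
        ang = np.linalg.norm(rv)
        if np.degrees(ang) > _MIN_AXIS_ANGLE_DEG:
            axes.append(rv / ang)
    if len(axes) < 2:
        return np.zeros(3)
    axes = np.asarray(axes)
    s = np.linalg.svd(axes, compute_uv=False)
    out = np.zeros(3)
    out[:len(s)] = s / np.sqrt(len(axes))
    return out


class HandEyeCalibration:
    """AX = YB solver over a batch of paired poses.

    Parameters
    ----------
    pairs : sequence of PairedPose
    min_pairs : int
        Session policy; the solver refuses fewer pairs and states how to
        override.  The mathematical minimum of 3 is always enforced.
    refine : bool
        Joint LM refinement of all 12 parameters after the linear solve.
    axis_gate : float
        Minimum normalised second singular value of the stacked rotation
        axes of {A_i}; below it the motion spans fewer than two
        independent rotation directions and the problem is unsolvable.
    """

    def __init__(self, pairs: Sequence[PairedPose], *,
                 min_pairs: int = DEFAULT_MIN_PAIRS, refine: bool = True,
                 axis_gate: float = 0.1, n_dropped: int = 0):
        pairs = list(pairs)
        if len(pairs) < max(3, min_pairs):
            raise InsufficientPairsError(
                f"got {len(pairs)} paired poses; the coregistration session "
                f"requires at least {min_pairs} head positions from each "
                "device (override with min_pairs=, mathematical minimum 3)")
        self.pairs = pairs
        self.refine = refine
        self.axis_gate = axis_gate
        self.n_dropped = n_dropped
        # stacked measurement arrays for the vectorised solvers
        self._RA = np.stack([p.A.rotation for p in pairs])
        self._tA = np.stack([p.A.translation for p in pairs])
        self._RB = np.stack([p.B.rotation for p in pairs])
        self._tB = np.stack([p.B.translation for p in pairs])

    def fit(self) -> CoregistrationResults:
        sv = _axis_spread(self.pairs)
        if sv[1] <= self.axis_gate:
            raise DegenerateMotionError(
                "rotation axes of the tracker measurements span fewer than 2 "
                f"independent directions (normalised axis singular values "
                f"{np.array_str(sv, precision=3)}); vary the head orientation "
                "during the session")
        RX, RY = self._solve_rotations()
        tX, tY, cond = self._solve_translations(RX, RY)
        X = RigidTransform(RX, tX, _skip_check=True)
        Y = RigidTransform(RY, tY, _skip_check=True)
        if self.refine:
            X, Y = self._refine(X, Y)
        drot_deg, dt = self._discrepancies(X.rotation, X.translation,
                                           Y.rotation, Y.translation)
        rot_res = np.linalg.norm(drot_deg, axis=1)
        tr_res = np.linalg.norm(dt, axis=1)
        return CoregistrationResults(
            X=X, Y=Y, rot_residuals_deg=rot_res, trans_residuals_mm=tr_res,
            n_pairs=len(self.pairs), n_dropped=self.n_dropped,
            condition_number=cond, axis_singular_values=sv,
            refined=self.refine)

    # -- linear rotation solve ----------------------------------------
    def _solve_rotations(self) -> tuple[np.ndarray, np.ndarray]:
        I3 = np.eye(3)
        rows = []
        for p in self.pairs:
            # vec(RX RA) = (RA^T (x) I) vec(RX);  vec(RB RY) = (I (x) RB) vec(RY)
            rows.append(np.hstack([np.kron(p.A.rotation.T, I3),
                                   -np.kron(I3, p.B.rotation)]))
        K = np.vstack(rows)
        _, _, vt = np.linalg.svd(K, full_matrices=False)
        v = vt[-1]
        Mx, My = _unvec(v[:9]), _unvec(v[9:])
        # common scale/sign: a rotation has determinant +1
        det = np.linalg.det(Mx)
        if abs(det) < 1e-12:
            raise DegenerateMotionError("rotation system is rank deficient")
        s = np.sign(det) / abs(det) ** (1.0 / 3.0)
        return _project_so3(s * Mx), _project_so3(s * My)

    # -- induced translation system -----------------------------------
    def _solve_translations(self, RX: np.ndarray, RY: np.ndarray):
        I3 = np.eye(3)
        A_blocks, b_blocks = [], []
        for p in self.pairs:
            A_blocks.append(np.hstack([I3, -p.B.rotation]))
            b_blocks.append(p.B.translation - RX @ p.A.translation)
        M = np.vstack(A_blocks)
        rhs = np.concatenate(b_blocks)
        sol, _, _, sv = np.linalg.lstsq(M, rhs, rcond=None)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        return sol[:3], sol[3:], cond

    # -- joint LM refinement ------------------------------------------
    def _discrepancies(self, RX, tX, RY, tY):
        """Per-pair rotvec angle (deg, n x 3) and translation gap (mm, n x 3)
        between X.A_i and B_i.Y, fully vectorised."""
        Rl = np.einsum("ij,njk->nik", RX, self._RA)
        Rr = np.einsum("nij,jk->nik", self._RB, RY)
        M = np.einsum("nji,njk->nik", Rl, Rr)  # Rl^T Rr
        drot = np.degrees(Rotation.from_matrix(M).as_rotvec())
        tl = self._tA @ RX.T + tX
        tr = np.einsum("nij,j->ni", self._RB, tY) + self._tB
        return drot, tl - tr

    def _residuals(self, p: np.ndarray) -> np.ndarray:
        RX = Rotation.from_rotvec(p[:3]).as_matrix()
        RY = Rotation.from_rotvec(p[6:9]).as_matrix()
        drot, dt = self._discrepancies(RX, p[3:6], RY, p[9:12])
        return np.concatenate([drot.ravel(), dt.ravel()])

    def _refine(self, X: RigidTransform, Y: RigidTransform):
        p0 = np.concatenate([Rotation.from_matrix(X.rotation).as_rotvec(),
                             X.translation,
                             Rotation.from_matrix(Y.rotation).as_rotvec(),
                             Y.translation])
        sol = least_squares(self._residuals, p0, method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        return (RigidTransform.from_rotvec(sol.x[:3], sol.x[3:6]),
                RigidTransform.from_rotvec(sol.x[6:9], sol.x[9:12]))


def solve(pairs: Sequence[PairedPose],
          min_pairs: int = DEFAULT_MIN_PAIRS, **kw) -> CoregistrationResults:
    """Functional wrapper: ``HandEyeCalibration(pairs, min_pairs=...).fit()``."""
    return HandEyeCalibration(pairs, min_pairs=min_pairs, **kw).fit()


def to_tracker(sol: CoregistrationResults, b: RigidTransform) -> RigidTransform:
    """Map a camera-frame head pose into the tracker frame (X^-1 . B)."""
    return sol.to_tracker(b)


def pair_streams(tracker: Sequence[tuple[float, RigidTransform]],
                 camera: Sequence[tuple[float, RigidTransform]],
                 tolerance_s: float) -> tuple[list[PairedPose], int]:
    """Nearest-neighbour timestamp pairing of two pose streams.

    Each camera sample is matched to the closest tracker sample; matches
    with |dt| above ``tolerance_s`` (default policy: half a frame period)
    are dropped.  Returns (pairs, n_dropped).
    """
    if not tracker or not camera:
        return [], len(tracker) + len(camera)
    t_ts = np.array([t for t, _ in tracker])
    pairs, dropped = [], 0
    for ts, B in camera:
        j = int(np.argmin(np.abs(t_ts - ts)))
        dt = float(ts - t_ts[j])
        if abs(dt) > tolerance_s:
            dropped += 1
            continue
        pairs.append(PairedPose(A=tracker[j][1], B=B, timestamp=ts, dt=dt))
    return pairs, dropped


# ---------------------------------------------------------------------------
# fiducial (point-based) registration
# ---------------------------------------------------------------------------

def fiducial_register(image_space: np.ndarray, tracker_space: np.ndarray
                      ) -> tuple[RigidTransform, float]:
    """Closed-form absolute-orientation registration of matched fiducials.

    The neuronavigation convention uses three anatomical fiducials
    (nasion, right and left ear tragus) digitised in both image and
    tracker space.  Returns the least-squares rigid transform mapping
    tracker-space points into image space and the fiducial registration
    error, FRE = RMS residual in mm.
    """
    P = np.asarray(image_space, dtype=float)
    Q = np.asarray(tracker_space, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise ValueError("need matched Nx3 point sets with N >= 3")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    if np.linalg.matrix_rank(Qc, tol=1e-9 * max(1.0, np.abs(Qc).max())) < 2:
        raise DegenerateMotionError("fiducials are collinear; registration is "
                                    "under-determined")
    H = Qc.T @ Pc
    u, _, vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cp - R @ cq
    T = RigidTransform(R, t, _skip_check=True)
    fre = float(np.sqrt(np.mean(np.sum((T.apply(Q) - P) ** 2, axis=1))))
    return T, fre
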