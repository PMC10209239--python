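"""Tracking quality metrics: stability, jitter, and target-revisit accuracy.

Stability of a nominally static acquisition is summarised by the sample
standard deviation of each pose coordinate about its mean, plus the SD of
the Euclidean distance of each sample from the mean position (both are
reported because the two conventions differ and both appear in practice).
Jitter is the 95% interval of each coordinate, defined as 1.96 times its
sample SD.  Revisit accuracy summarises repeated repositionings of a
tracked coil onto a predefined target: per-visit Euclidean distance and
per-angle differences, with mean, SD and the 95th percentile, judged
against a 3 mm / 3 deg acceptance window.

Sample SDs use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .filters import COORD_NAMES, PoseStream
from .geometry import EulerPose

TRANSLATION = slice(0, 3)
ANGLES = slice(3, 6)


def _angle_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise angle difference wrapped to [-180, 180)."""
    return (a - b + 180.0) % 360.0 - 180.0


@dataclass
class StabilityReport:
    """Per-coordinate SDs plus the Euclidean-distance SD of a static stream."""

    sd: dict[str, float]            # x,y,z in mm; yaw,pitch,roll in deg
    euclidean_sd_mm: float
    mean_pose: dict[str, float]
    n: int
    duration_s: float
    filter_provenance: str

    def summary(self) -> str:
        lines = [
            "Static-pose stability",
            "=" * 46,
            f"n = {self.n} samples over {self.duration_s:.1f} s   "
            f"filter: {self.filter_provenance}",
            "coordinate        SD",
        ]
        units = ["mm", "mm", "mm", "deg", "deg", "deg"]
        for name, u in zip(COORD_NAMES, units):
            lines.append(f"  {name:<8} {self.sd[name]:12.6f} {u}")
        lines.append(f"  distance {self.euclidean_sd_mm:12.6f} mm "
                     "(SD of |r - mean r|)")
        return "\n".join(lines)


@dataclass
class RevisitReport:
    """Accuracy of repeated returns to a predefined target pose."""

    distances_mm: np.ndarray
    angle_diffs_deg: np.ndarray     # n_visits x 3 (yaw, pitch, roll)
    mean_distance_mm: float
    sd_distance_mm: float
    p95_distance_mm: float
    mean_angle_deg: dict[str, float]
    sd_angle_deg: dict[str, float]
    p95_angle_deg: dict[str, float]
    n_visits: int
    within_window: np.ndarray       # per-visit pass/fail against 3 mm / 3 deg
    tol_mm: float
    tol_deg: float

    def summary(self) -> str:
        lines = [
            "Target-revisit accuracy",
            "=" * 46,
            f"visits: {self.n_visits}   window: {self.tol_mm} mm / {self.tol_deg} deg"
            f"   within window: {int(self.within_window.sum())}/{self.n_visits}",
            f"distance: mean {self.mean_distance_mm:.4f} mm, "
            f"SD {self.sd_distance_mm:.4f} mm, "
            f"95th pct {self.p95_distance_mm:.4f} mm",
        ]
        for a in ("yaw", "pitch", "roll"):
            lines.append(f"{a}: mean {self.mean_angle_deg[a]:.4f} deg, "
                         f"SD {self.sd_angle_deg[a]:.4f} deg, "
                         f"95th pct {self.p95_angle_deg[a]:.4f} deg")
        return "\n".join(lines)


def stability(stream: PoseStream) -> StabilityReport:
    """Stability SDs of a static acquisition (valid samples only)."""
    data = stream.data[stream.valid]
    n = len(data)
    if n < 2:
        raise ValueError("stability needs at least 2 valid samples")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    dist = np.linalg.norm(data[:, TRANSLATION] - mean[TRANSLATION], axis=1)
    ts = stream.timestamps[stream.valid]
    return StabilityReport(
        sd={name: float(s) for name, s in zip(COORD_NAMES, sd)},
        euclidean_sd_mm=float(dist.std(ddof=1)),
        mean_pose={name: float(m) for name, m in zip(COORD_NAMES, mean)},
        n=n,
        duration_s=float(ts[-1] - ts[0]),
        filter_provenance=stream.provenance,
    )


def jitter(stream: PoseStream) -> dict[str, float]:
    """95% jitter interval per coordinate: exactly 1.96 x sample SD."""
    rep = stability(stream)
    return {name: 1.96 * rep.sd[name] for name in COORD_NAMES}


def revisit_accuracy(target: EulerPose, visits: Sequence[EulerPose],
                     tol_mm: float = 3.0, tol_deg: float = 3.0) -> RevisitReport:
    """Distance and angle errors of repeated returns to ``target``.

    The 3-4 mm / 3-4 deg operational envelope for the 95th percentile is
    reported through the percentiles, not enforced.
    """
    if len(visits) < 1:
        raise ValueError("need at least one visit")
    tt = target.translation()
    ta = target.angles()
    dists = np.array([np.linalg.norm(v.translation() - tt) for v in visits])
    angs = np.array([_angle_diff_deg(v.angles(), ta) for v in visits])
    abs_angs = np.abs(angs)
    within = (dists <= tol_mm) & np.all(abs_angs <= tol_deg, axis=1)
    ddof = 1 if len(visits) > 1 else 0
    names = ("yaw", "pitch", "roll")
    return RevisitReport(
        distances_mm=dists,
        angle_diffs_deg=angs,
        mean_distance_mm=float(dists.mean()),
        sd_distance_mm=float(dists.std(ddof=ddof)),
        p95_distance_mm=float(np.percentile(dists, 95)),
        mean_angle_deg={n: float(abs_angs[:, i].mean()) for i, n in enumerate(names)},
        sd_angle_deg={n: float(abs_angs[:, i].std(ddof=ddof)) for i, n in enumerate(names)},
        p95_angle_deg={n: float(np.percentile(abs_angs[:, i], 95)) for i, n in enumerate(names)},
        n_visits=len(visits),
        within_window=within,
        tol_mm=tol_mm,
        tol_deg=tol_deg,
    )


def target_reached(current: EulerPose, target: EulerPose,
                   tol_mm: float = 3.0, tol_deg: float = 3.0
                   ) -> tuple[bool, dict[str, float]]:
    """Inclusive acceptance test against the 3 mm / 3 deg window.

    True iff the Euclidean distance is <= tol_mm AND every angle
    difference is <= tol_deg.  The margins (tolerance minus error;
    negative when violated) support guidance displays.
    """
    dist = float(np.linalg.norm(current.translation() - target.translation()))
    dang = np.abs(_angle_diff_deg(current.angles(), target.angles()))
    reached = dist <= tol_mm and bool(np.all(dang <= tol_deg))
    margins = {
        "distance_mm": tol_mm - dist,
        "yaw_deg": float(tol_deg - dang[0]),
        "pitch_deg": float(tol_deg - dang[1]),
        "roll_deg": float(tol_deg - dang[2]),
    }
    return reached, margins
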