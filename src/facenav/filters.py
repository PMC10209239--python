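"""Real-time smoothing of 6-DoF pose streams.

The primary filter is the Savitzky-Golay filter — least-squares fit of a
low-degree polynomial over a sliding window, order 1 and window 5 by
default, the configuration found to suppress jitter with no noticeable
delay at navigation frame rates.  A per-coordinate constant-velocity
Kalman filter and a rolling-window Grubbs outlier filter are provided as
alternatives for comparison.

All filters preserve timestamps and sample count.  In ``causal`` mode the
output at time t depends only on samples at times <= t; the first
``window - 1`` samples are passed through unchanged and flagged
``unfiltered`` rather than fabricated from padding — this is a
medical-navigation stream, an invented pose is worse than a raw one.

Angles are filtered on unwrapped values (seam threshold 180 deg) so a
stream hovering near +/-180 deg does not alias through the seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import savgol_coeffs
from scipy.stats import t as t_dist

from .geometry import EulerPose

COORD_NAMES = ("x", "y", "z", "yaw", "pitch", "roll")
ANGLE_COLUMNS = (3, 4, 5)


class FilterConfigError(ValueError):
    """Invalid filter configuration (window/order/alpha constraints)."""


@dataclass
class FilterConfig:
    """Configuration for the pose-stream filters.

    kind: 'savgol' | 'kalman' | 'grubbs' | 'none'
    window: sliding-window length in frames (odd, >= order + 2 for savgol)
    order: polynomial degree (savgol)
    mode: 'causal' evaluates the fit at the newest sample; 'centered' at the
        window midpoint (the textbook Savitzky-Golay definition)
    process_var / measurement_var: Kalman variances (units of the coordinate)
    alpha: Grubbs test significance level
    """

    kind: Literal["savgol", "kalman", "grubbs", "none"] = "savgol"
    window: int = 5
    order: int = 1
    mode: Literal["causal", "centered"] = "causal"
    process_var: float = 1e-3
    measurement_var: float = 1.0
    alpha: float = 0.05

    def validate(self) -> "FilterConfig":
        if self.kind == "savgol":
            if self.window % 2 == 0:
                raise FilterConfigError("savgol window must be odd")
            if self.order >= self.window:
                raise FilterConfigError("savgol order must be < window")
        if self.kind == "kalman" and (self.process_var <= 0 or self.measurement_var <= 0):
            raise FilterConfigError("Kalman variances must be positive")
        if self.kind == "grubbs":
            if self.window < 7:
                raise FilterConfigError("Grubbs window must be >= 7 (test power)")
            if not 0.0 < self.alpha < 1.0:
                raise FilterConfigError("Grubbs alpha must be in (0, 1)")
        return self

    def provenance(self) -> str:
        if self.kind == "savgol":
            return f"savgol(window={self.window},order={self.order},mode={self.mode})"
        if self.kind == "kalman":
            return f"kalman(q={self.process_var},r={self.measurement_var})"
        if self.kind == "grubbs":
            return f"grubbs(window={self.window},alpha={self.alpha})"
        return "none"


@dataclass
class PoseStream:
    """Timestamped sequence of 6-DoF poses at a nominal frame rate.

    ``data`` is an (n, 6) array in the canonical coordinate order
    (x, y, z in mm; yaw, pitch, roll in deg).  ``valid`` marks samples that
    passed the upstream residual gate; ``unfiltered`` marks samples a
    causal filter emitted unchanged during startup.
    """

    timestamps: np.ndarray
    data: np.ndarray
    rate_hz: Optional[float] = None
    valid: np.ndarray = None
    unfiltered: np.ndarray = None
    provenance: str = "raw"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.timestamps)
        if self.data.shape != (n, 6):
            raise ValueError(f"data must be ({n}, 6)")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.valid = (np.ones(n, dtype=bool) if self.valid is None
                      else np.asarray(self.valid, dtype=bool))
        self.unfiltered = (np.zeros(n, dtype=bool) if self.unfiltered is None
                           else np.asarray(self.unfiltered, dtype=bool))
        if not np.all(np.isfinite(self.data[self.valid])):
            raise ValueError("valid samples must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)

    @classmethod
    def from_poses(cls, poses: Sequence[EulerPose],
                   rate_hz: Optional[float] = None,
                   provenance: str = "raw") -> "PoseStream":
        ts = np.array([p.timestamp if p.timestamp is not None else i
                       for i, p in enumerate(poses)], dtype=float)
        data = np.array([p.as_array() for p in poses])
        valid = np.array([p.valid for p in poses])
        return cls(ts, data, rate_hz=rate_hz, valid=valid, provenance=provenance)

    def poses(self) -> list[EulerPose]:
        return [EulerPose(*row, timestamp=t, valid=bool(v))
                for row, t, v in zip(self.data, self.timestamps, self.valid)]

    def _replace_data(self, data: np.ndarray, unfiltered: np.ndarray,
                      provenance: str) -> "PoseStream":
        return PoseStream(self.timestamps.copy(), data, rate_hz=self.rate_hz,
                          valid=self.valid.copy(), unfiltered=unfiltered,
                          provenance=provenance)


def _unwrap_angles(data: np.ndarray) -> np.ndarray:
    out = data.copy()
    for c in ANGLE_COLUMNS:
        out[:, c] = np.degrees(np.unwrap(np.radians(out[:, c])))
    return out


def _rewrap_angles(data: np.ndarray) -> np.ndarray:
    out = data.copy()
    for c in ANGLE_COLUMNS:
        out[:, c] = (out[:, c] + 180.0) % 360.0 - 180.0
    return out


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------

def savgol_weights(window: int, order: int,
                   mode: Literal["causal", "centered"] = "causal") -> np.ndarray:
    """Least-squares polynomial-fit weights, ordered oldest -> newest.

    ``causal`` evaluates the fitted polynomial at the newest sample,
    ``centered`` at the window midpoint.  For order 1, window 5, centered,
    the weights are the plain moving average (1/5, ..., 1/5).
    """
    pos = window - 1 if mode == "causal" else (window - 1) // 2
    return savgol_coeffs(window, order, pos=pos, use="dot")


def savgol(stream: PoseStream, cfg: Optional[FilterConfig] = None) -> PoseStream:
    """Savitzky-Golay smoothing of every coordinate independently."""
    cfg = (cfg or FilterConfig(kind="savgol")).validate()
    if cfg.kind != "savgol":
        raise FilterConfigError(f"expected savgol config, got {cfg.kind}")
    w, n = cfg.window, len(stream)
    weights = savgol_weights(cfg.window, cfg.order, cfg.mode)
    src = _unwrap_angles(stream.data)
    out = src.copy()
    unfiltered = np.zeros(n, dtype=bool)
    if cfg.mode == "causal":
        for i in range(n):
            if i < w - 1:
                unfiltered[i] = True
                continue
            out[i] = weights @ src[i - w + 1:i + 1]
    else:
        half = (w - 1) // 2
        for i in range(n):
            if i < half or i >= n - half:
                unfiltered[i] = True
                continue
            out[i] = weights @ src[i - half:i + half + 1]
    return stream._replace_data(_rewrap_angles(out), unfiltered, cfg.provenance())


# ---------------------------------------------------------------------------
# Kalman (per-coordinate constant velocity)
# ---------------------------------------------------------------------------

def kalman(stream: PoseStream, cfg: Optional[FilterConfig] = None) -> PoseStream:
    """Constant-velocity linear Kalman filter applied to each coordinate.

    State [position, velocity]; the process noise enters through the
    velocity (white-acceleration model).  Strictly causal by construction.
    """
    cfg = (cfg or FilterConfig(kind="kalman")).validate()
    if cfg.kind != "kalman":
        raise FilterConfigError(f"expected kalman config, got {cfg.kind}")
    n = len(stream)
    src = _unwrap_angles(stream.data)
    out = src.copy()
    ts = stream.timestamps
    F_template = np.eye(2)
    H = np.array([[1.0, 0.0]])
    R = np.array([[cfg.measurement_var]])
    for c in range(6):
        x = np.array([src[0, c], 0.0])
        P = np.diag([cfg.measurement_var, cfg.measurement_var])
        out[0, c] = x[0]
        for i in range(1, n):
            dt = ts[i] - ts[i - 1]
            F = F_template.copy()
            F[0, 1] = dt
            Q = cfg.process_var * np.array([[dt ** 3 / 3, dt ** 2 / 2],
                                            [dt ** 2 / 2, dt]])
            x = F @ x
            P = F @ P @ F.T + Q
            S = H @ P @ H.T + R
            K = P @ H.T / S
            innov = src[i, c] - x[0]
            x = x + (K * innov).ravel()
            P = (np.eye(2) - K @ H) @ P
            out[i, c] = x[0]
    return stream._replace_data(_rewrap_angles(out), np.zeros(n, dtype=bool),
                                cfg.provenance())


# ---------------------------------------------------------------------------
# Grubbs rolling outlier rejection
# ---------------------------------------------------------------------------

def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution."""
    tcrit = t_dist.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tcrit ** 2 / (n - 2 + tcrit ** 2))


def grubbs(stream: PoseStream, cfg: Optional[FilterConfig] = None) -> PoseStream:
    """Rolling-window Grubbs outlier test per coordinate.

    Within each trailing window the single most extreme sample is tested;
    if it is the newest sample and exceeds the critical value it is
    replaced by the window median and flagged as unfiltered=False but
    recorded in the provenance.  Zero-variance windows are skipped (no
    outlier can be declared without spread).
    """
    cfg = (cfg or FilterConfig(kind="grubbs", window=9)).validate()
    if cfg.kind != "grubbs":
        raise FilterConfigError(f"expected grubbs config, got {cfg.kind}")
    w, n = cfg.window, len(stream)
    src = _unwrap_angles(stream.data)
    out = src.copy()
    gcrit = grubbs_critical(w, cfg.alpha)
    flagged = np.zeros(n, dtype=bool)
    for c in range(6):
        for i in range(w - 1, n):
            win = src[i - w + 1:i + 1, c]
            sd = win.std(ddof=1)
            if sd == 0.0:
                continue
            g_new = abs(win[-1] - win.mean()) / sd
            if g_new > gcrit and g_new >= np.max(np.abs(win - win.mean())) / sd - 1e-15:
                out[i, c] = np.median(win)
                flagged[i] = True
    res = stream._replace_data(_rewrap_angles(out), np.zeros(n, dtype=bool),
                               cfg.provenance())
    res.outlier_flags = flagged
    return res


# ---------------------------------------------------------------------------
# filter dispatch and jitter-reduction metric
# ---------------------------------------------------------------------------

def apply_filter(stream: PoseStream, cfg: FilterConfig) -> PoseStream:
    cfg.validate()
    if cfg.kind == "none":
        return stream._replace_data(stream.data.copy(),
                                    np.zeros(len(stream), dtype=bool), "none")
    return {"savgol": savgol, "kalman": kalman, "grubbs": grubbs}[cfg.kind](stream, cfg)


def jitter_reduction(raw: PoseStream, filtered: PoseStream) -> dict:
    """Per-coordinate SD comparison between a raw and a filtered stream.

    Reports both directions: how much higher the raw SD is than the
    filtered SD, ``(SD_raw - SD_filt) / SD_filt`` in percent, and the
    complementary reduction ``(SD_raw - SD_filt) / SD_raw``.  A zero
    filtered SD is reported as an infinite-improvement flag.
    """
    if len(raw) != len(filtered):
        raise ValueError("streams must be aligned")
    sd_raw = raw.data.std(axis=0, ddof=1)
    sd_filt = filtered.data.std(axis=0, ddof=1)
    raw_higher_pct, reduction_pct, infinite = {}, {}, {}
    for i, name in enumerate(COORD_NAMES):
        if sd_filt[i] == 0.0:
            infinite[name] = sd_raw[i] > 0
            raw_higher_pct[name] = np.inf if sd_raw[i] > 0 else 0.0
        else:
            infinite[name] = False
            raw_higher_pct[name] = 100.0 * (sd_raw[i] - sd_filt[i]) / sd_filt[i]
        reduction_pct[name] = (100.0 * (sd_raw[i] - sd_filt[i]) / sd_raw[i]
                               if sd_raw[i] > 0 else 0.0)
    finite = [v for v in raw_higher_pct.values() if np.isfinite(v)]
    return {
        "raw_higher_pct": raw_higher_pct,
        "reduction_pct": reduction_pct,
        "infinite_improvement": infinite,
        "average_raw_higher_pct": float(np.mean(finite)) if finite else np.inf,
    }
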