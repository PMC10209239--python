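"""Plain-text file formats for the pipeline.

Everything is CSV or a documented key-value text format: navigation logs
have no standard interchange container, and diffable text makes every
stage auditable.  All numbers are written with 17 significant digits so a
write/read round-trip is bit-exact for double precision.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .camera import CameraCalibrationResults, CameraIntrinsics
from .characterization import RevisitReport, StabilityReport
from .coregistration import CoregistrationResults, PairedPose
from .filters import COORD_NAMES, PoseStream
from .geometry import RigidTransform
from .headpose import LANDMARK_NAMES, LandmarkObservation

PathLike = Union[str, Path]

_FMT = "%.17g"


def _f(x: float) -> str:
    return _FMT % x


def _write_kv(path: PathLike, sections: dict[str, dict[str, str]]) -> None:
    lines = []
    for section, kv in sections.items():
        lines.append(f"[{section}]")
        for k, v in kv.items():
            lines.append(f"{k} = {v}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def _read_kv(path: PathLike) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: Optional[str] = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            k, v = line.split("=", 1)
            sections[current][k.strip()] = v.strip()
    return sections


def _vec_str(v: np.ndarray) -> str:
    return " ".join(_f(x) for x in np.asarray(v, dtype=float).ravel())


def _vec_parse(s: str) -> np.ndarray:
    return np.array([float(x) for x in s.split()])


# ---------------------------------------------------------------------------
# camera calibration result file
# ---------------------------------------------------------------------------

def write_calibration(path: PathLike, res: CameraCalibrationResults) -> None:
    k = res.intrinsics
    sec = {
        "camera": {
            "matrix_row_major": _vec_str(k.matrix()),
            "distortion_k1_k2_p1_p2_k3": _vec_str(k.dist),
            "image_size": ("" if k.image_size is None
                           else f"{k.image_size[0]} {k.image_size[1]}"),
        },
        "errors": {
            "mean_px": _f(res.mean_error_px),
            "rms_px": _f(res.rms_error_px),
            "per_view_mean_px": _vec_str(res.per_view_mean_px),
            "per_view_rms_px": _vec_str(res.per_view_rms_px),
            "per_view_mean_mm": _vec_str(res.per_view_mean_mm),
        },
    }
    _write_kv(path, sec)


def read_calibration(path: PathLike) -> CameraIntrinsics:
    sec = _read_kv(path)
    m = _vec_parse(sec["camera"]["matrix_row_major"]).reshape(3, 3)
    dist = _vec_parse(sec["camera"]["distortion_k1_k2_p1_p2_k3"])
    size_s = sec["camera"].get("image_size", "")
    size = tuple(int(x) for x in size_s.split()) if size_s else None
    return CameraIntrinsics(fx=m[0, 0], fy=m[1, 1], cx=m[0, 2], cy=m[1, 2],
                            skew=m[0, 1], dist=dist, image_size=size)


# ---------------------------------------------------------------------------
# coregistration solution file
# ---------------------------------------------------------------------------

def write_solution(path: PathLike, res: CoregistrationResults) -> None:
    sec = {
        "solution": {
            "X_camera_from_tracker_row_major": _vec_str(res.X.as_matrix()),
            "Y_headpose_from_marker_row_major": _vec_str(res.Y.as_matrix()),
        },
        "residuals": {
            "n_pairs": str(res.n_pairs),
            "n_dropped": str(res.n_dropped),
            "mean_rotation_deg": _f(res.mean_rot_residual_deg),
            "mean_translation_mm": _f(res.mean_trans_residual_mm),
            "max_rotation_deg": _f(float(res.rot_residuals_deg.max())),
            "max_translation_mm": _f(float(res.trans_residuals_mm.max())),
            "condition_number": _f(res.condition_number),
        },
    }
    _write_kv(path, sec)


def read_solution(path: PathLike) -> tuple[RigidTransform, RigidTransform]:
    sec = _read_kv(path)
    X = RigidTransform.from_matrix(
        _vec_parse(sec["solution"]["X_camera_from_tracker_row_major"]).reshape(4, 4))
    Y = RigidTransform.from_matrix(
        _vec_parse(sec["solution"]["Y_headpose_from_marker_row_major"]).reshape(4, 4))
    return X, Y


# ---------------------------------------------------------------------------
# landmark stream CSV: timestamp, name, u, v, confidence
# ---------------------------------------------------------------------------

def write_landmarks(path: PathLike, observations: Sequence[LandmarkObservation]
                    ) -> None:
    rows = ["timestamp,name,u,v,confidence"]
    for obs in observations:
        for name in LANDMARK_NAMES:
            u, v = obs.points[name]
            c = 1.0 if obs.confidence is None else obs.confidence.get(name, 1.0)
            rows.append(f"{_f(obs.timestamp)},{name},{_f(u)},{_f(v)},{_f(c)}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_landmarks(path: PathLike) -> list[LandmarkObservation]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for ts, grp in df.groupby("timestamp", sort=True):
        pts = {r["name"]: np.array([r["u"], r["v"]]) for _, r in grp.iterrows()}
        conf = {r["name"]: float(r["confidence"]) for _, r in grp.iterrows()}
        out.append(LandmarkObservation(timestamp=float(ts), points=pts,
                                       confidence=conf))
    return out


# ---------------------------------------------------------------------------
# paired-pose CSV: timestamp, source, 12 row-major entries (R then t)
# ---------------------------------------------------------------------------

def _transform_row(T: RigidTransform) -> str:
    r = T.rotation.ravel()
    t = T.translation
    return ",".join(_f(x) for x in np.concatenate([r, t]))


def _transform_from_values(vals: Sequence[float]) -> RigidTransform:
    vals = np.asarray(vals, dtype=float)
    return RigidTransform(vals[:9].reshape(3, 3), vals[9:])


def write_pairs(path: PathLike, pairs: Sequence[PairedPose]) -> None:
    hdr = ("timestamp,source," +
           ",".join(f"r{i}{j}" for i in range(3) for j in range(3)) +
           ",tx,ty,tz")
    rows = [hdr]
    for p in pairs:
        rows.append(f"{_f(p.timestamp)},tracker,{_transform_row(p.A)}")
        rows.append(f"{_f(p.timestamp)},camera,{_transform_row(p.B)}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_pairs(path: PathLike, pairing_tolerance_s: float = 1.0
               ) -> tuple[list[PairedPose], int]:
    """Read and pair the two sources by nearest timestamp."""
    from .coregistration import pair_streams
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]
    tracker, camera = [], []
    for _, r in df.iterrows():
        T = _transform_from_values(r[cols].to_numpy(dtype=float))
        (tracker if r["source"] == "tracker" else camera).append(
            (float(r["timestamp"]), T))
    return pair_streams(tracker, camera, pairing_tolerance_s)


# ---------------------------------------------------------------------------
# pose stream CSV
# ---------------------------------------------------------------------------

def write_stream(path: PathLike, stream: PoseStream) -> None:
    rows = [f"# provenance: {stream.provenance}"]
    if stream.rate_hz is not None:
        rows.append(f"# rate_hz: {_f(stream.rate_hz)}")
    rows.append("timestamp," + ",".join(COORD_NAMES) + ",valid,unfiltered")
    for i in range(len(stream)):
        vals = ",".join(_f(x) for x in stream.data[i])
        rows.append(f"{_f(stream.timestamps[i])},{vals},"
                    f"{int(stream.valid[i])},{int(stream.unfiltered[i])}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_stream(path: PathLike) -> PoseStream:
    text = Path(path).read_text()
    provenance, rate = "raw", None
    body = []
    for line in text.splitlines():
        if line.startswith("# provenance:"):
            provenance = line.split(":", 1)[1].strip()
        elif line.startswith("# rate_hz:"):
            rate = float(line.split(":", 1)[1])
        elif line and not line.startswith("#"):
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)), float_precision="round_trip")
    return PoseStream(
        timestamps=df["timestamp"].to_numpy(dtype=float),
        data=df[list(COORD_NAMES)].to_numpy(dtype=float),
        rate_hz=rate,
        valid=df["valid"].to_numpy(dtype=bool),
        unfiltered=df["unfiltered"].to_numpy(dtype=bool),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# characterization reports
# ---------------------------------------------------------------------------

def write_stability(path: PathLike, rep: StabilityReport) -> None:
    kv = {f"sd_{name}": _f(rep.sd[name]) for name in COORD_NAMES}
    kv["euclidean_sd_mm"] = _f(rep.euclidean_sd_mm)
    kv["n"] = str(rep.n)
    kv["duration_s"] = _f(rep.duration_s)
    kv["filter"] = rep.filter_provenance
    _write_kv(path, {"stability": kv})


def stability_table(reports: dict[str, StabilityReport]) -> pd.DataFrame:
    """Table of per-condition stability rows x six SD columns.

    Keys of ``reports`` label the rows (e.g. 'camera@100cm/filtered').
    """
    cols = {"SD X (mm)": "x", "SD Y (mm)": "y", "SD Z (mm)": "z",
            "SD Yaw (deg)": "yaw", "SD Pitch (deg)": "pitch",
            "SD Roll (deg)": "roll"}
    data = {label: [rep.sd[c] for c in cols.values()]
            for label, rep in reports.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=list(cols))


def write_revisit(path: PathLike, rep: RevisitReport) -> None:
    kv = {
        "n_visits": str(rep.n_visits),
        "mean_distance_mm": _f(rep.mean_distance_mm),
        "sd_distance_mm": _f(rep.sd_distance_mm),
        "p95_distance_mm": _f(rep.p95_distance_mm),
        "within_window": str(int(rep.within_window.sum())),
        "tol_mm": _f(rep.tol_mm),
        "tol_deg": _f(rep.tol_deg),
    }
    for a in ("yaw", "pitch", "roll"):
        kv[f"mean_{a}_deg"] = _f(rep.mean_angle_deg[a])
        kv[f"sd_{a}_deg"] = _f(rep.sd_angle_deg[a])
        kv[f"p95_{a}_deg"] = _f(rep.p95_angle_deg[a])
    _write_kv(path, {"revisit": kv})
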