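"""Milestone-based 3D localization and tracking from single-view 2D detections.

A single fluoroscopic projection gives only in-plane (x, y) coordinates.
The missing depth coordinate is recovered from a calibrated digital twin of
the vessel: virtual spherical "milestones" with known 3D coordinates are
placed at uniform arc-length spacing (a quarter of the robot length) along
the centerline.  Each 2D detection is mapped into the twin's world frame by
a similarity transform, matched to the closest milestone segment in-plane,
and assigned the depth interpolated along the centerline between the two
bracketing milestones (or snapped to the nearest milestone, for strict
closest-milestone fidelity).  A continuity gate — the robot cannot advance
faster than its no-slip corkscrew speed — resolves projection ambiguities
such as overlapping vessel limbs, and constant-velocity coasting bridges
detection dropouts up to a configurable horizon.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import SimilarityTransform

from .errors import CalibrationError, ConfigurationError, GeometryError
from .sizing import VesselProfile

_AXES = {"x": (1, 2, 0), "y": (0, 2, 1), "z": (0, 1, 2)}


@dataclass(frozen=True)
class Milestone:
    index: int
    position: np.ndarray  # (3,) mm
    arc_length_s: float  # mm
    radius: float  # marker size, mm


@dataclass(frozen=True)
class Detection:
    timestamp_ms: float
    u: float
    v: float
    confidence: float = 1.0


@dataclass(frozen=True)
class FrameCalibration:
    """Similarity transform between image pixels and world in-plane mm."""

    scale: float  # mm per px
    rotation_deg: float
    translation: tuple[float, float]  # mm
    projection_axis: str = "z"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise CalibrationError("scale must be positive")
        if self.projection_axis not in _AXES:
            raise CalibrationError(f"unknown projection axis {self.projection_axis!r}")

    @classmethod
    def identity(cls, projection_axis: str = "z") -> "FrameCalibration":
        return cls(1.0, 0.0, (0.0, 0.0), projection_axis)

    @property
    def _matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return self.scale * np.array(
            [[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]]
        )

    def image_to_world(self, uv) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        return uv @ self._matrix.T + np.asarray(self.translation)

    def world_to_image(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=float) - np.asarray(self.translation)
        return xy @ np.linalg.inv(self._matrix).T

    def project(self, points3d) -> np.ndarray:
        """Drop the projection axis: world 3D -> world in-plane 2D."""
        i, j, _ = _AXES[self.projection_axis]
        pts = np.asarray(points3d, dtype=float)
        return pts[..., [i, j]]

    def depth_index(self) -> int:
        return _AXES[self.projection_axis][2]


def calibrate_frames(image_points, world_points, projection_axis: str = "z"):
    """Least-squares similarity transform from fiducial pairs.

    Returns ``(FrameCalibration, residual_rms_mm)``.  Requires at least two
    non-coincident, non-collinear-degenerate fiducials.
    """
    src = np.asarray(image_points, dtype=float)
    dst = np.asarray(world_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise CalibrationError("need >=2 matched (image, world) fiducial pairs")
    if np.allclose(src, src[0]):
        raise CalibrationError("fiducials are coincident; transform is rank-deficient")
    tf = SimilarityTransform()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # estimate() rename in skimage
        ok = tf.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tf.params)) or tf.scale <= 0:
        raise CalibrationError("similarity estimation failed (degenerate fiducials)")
    cal = FrameCalibration(
        scale=float(tf.scale),
        rotation_deg=float(math.degrees(tf.rotation)),
        translation=(float(tf.translation[0]), float(tf.translation[1])),
        projection_axis=projection_axis,
    )
    residual = cal.image_to_world(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return cal, rms


def place_milestones(
    profile: VesselProfile,
    robot_length: float,
    spacing_fraction: float = 0.25,
    marker_radius: float | None = None,
) -> list[Milestone]:
    """Milestones at uniform arc-length spacing ≈ spacing_fraction·robot length.

    The first milestone sits at s = 0 and the set spans the full navigable
    extent; when the vessel length is not an exact multiple of the target
    spacing the gaps shrink uniformly so they stay exactly equal.
    """
    if robot_length <= 0 or spacing_fraction <= 0:
        raise GeometryError("robot_length and spacing_fraction must be positive")
    total = profile.total_length
    if total <= 0:
        raise GeometryError("degenerate (zero-length) centerline")
    spacing = spacing_fraction * robot_length
    n = max(2, int(math.ceil(total / spacing - 1e-9)) + 1)
    s_vals = np.linspace(0.0, total, n)
    radius = marker_radius if marker_radius is not None else spacing / 2.0
    pts = profile.point_at(s_vals)
    return [
        Milestone(index=i, position=pts[i], arc_length_s=float(s_vals[i]), radius=radius)
        for i in range(n)
    ]


@dataclass(frozen=True)
class Localization:
    position: np.ndarray  # (3,) mm
    s: float
    milestone_index: int
    in_plane_distance: float
    timestamp_ms: float
    ambiguous: bool = False


def localize_detection(
    det: Detection,
    cal: FrameCalibration,
    milestones: list[Milestone],
    prev: Localization | None = None,
    max_speed_mm_s: float | None = None,
    mode: str = "interpolate",
) -> Localization | None:
    """Locate one detection against the milestone chain.

    In-plane coordinates come from the calibrated detection itself; the
    depth coordinate is interpolated along the centerline between the
    bracketing milestones (``mode='interpolate'``) or taken from the single
    nearest milestone (``mode='snap'``).  With ``prev`` and
    ``max_speed_mm_s`` given, candidates outside the reachable arc-length
    window are rejected; returns None when no candidate survives the gate
    (the caller should coast).
    """
    if not milestones:
        raise ConfigurationError("milestone list is empty")
    if mode not in ("interpolate", "snap"):
        raise ConfigurationError(f"unknown localization mode {mode!r}")
    p = cal.image_to_world([det.u, det.v])
    ms_pos = np.stack([m.position for m in milestones])
    ms_s = np.array([m.arc_length_s for m in milestones])
    ms_ip = cal.project(ms_pos)
    depth_i = cal.depth_index()
    inplane_i = [i for i in range(3) if i != depth_i]

    gate = None
    if prev is not None and max_speed_mm_s is not None:
        dt_s = max(0.0, (det.timestamp_ms - prev.timestamp_ms) / 1e3)
        gate = (prev.s - max_speed_mm_s * dt_s, prev.s + max_speed_mm_s * dt_s)

    candidates: list[tuple[float, float, float, int]] = []  # (dist, s, depth, idx)
    if len(milestones) == 1:
        d = float(np.linalg.norm(p - ms_ip[0]))
        candidates.append((d, float(ms_s[0]), float(ms_pos[0, depth_i]), 0))
    else:
        for k in range(len(milestones) - 1):
            a, b = ms_ip[k], ms_ip[k + 1]
            ab = b - a
            denom = float(ab @ ab)
            t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
            s_cand = float(ms_s[k] + t * (ms_s[k + 1] - ms_s[k]))
            if gate is not None and not (gate[0] <= s_cand <= gate[1]):
                continue
            foot = a + t * ab
            dist = float(np.linalg.norm(p - foot))
            depth = float(
                ms_pos[k, depth_i] + t * (ms_pos[k + 1, depth_i] - ms_pos[k, depth_i])
            )
            idx = k if t < 0.5 else k + 1
            if mode == "snap":
                # closest-milestone fidelity: quantize the depth only; the
                # arc-length estimate stays continuous for the gate
                depth = float(ms_pos[idx, depth_i])
            candidates.append((dist, s_cand, depth, idx))
    if not candidates:
        return None
    dist, s_cand, depth, idx = min(candidates, key=lambda c: c[0])
    pos = np.empty(3)
    pos[inplane_i[0]] = p[0]
    pos[inplane_i[1]] = p[1]
    pos[depth_i] = depth
    return Localization(
        position=pos,
        s=s_cand,
        milestone_index=idx,
        in_plane_distance=dist,
        timestamp_ms=det.timestamp_ms,
    )


@dataclass
class Track:
    """Per-timestamp 3D trajectory with interpolation flags and latency."""

    data: pd.DataFrame
    n_segments: int

    @property
    def empty(self) -> bool:
        return self.data.empty


_TRACK_COLUMNS = [
    "t_ms",
    "x_mm",
    "y_mm",
    "z_mm",
    "s_mm",
    "milestone",
    "interpolated",
    "segment",
    "latency_ms",
]


def _interp_position(milestones: list[Milestone], s: float) -> np.ndarray:
    ms_s = np.array([m.arc_length_s for m in milestones])
    pts = np.stack([m.position for m in milestones])
    return np.array([np.interp(s, ms_s, pts[:, i]) for i in range(3)])


def track_stream(
    detections,
    cal: FrameCalibration,
    milestones: list[Milestone],
    max_speed_mm_s: float = 80.0,
    coast_horizon_ms: float = 500.0,
    frame_interval_ms: float | None = None,
    mode: str = "interpolate",
) -> Track:
    """Sequentially localize a detection stream with gating and coasting.

    ``detections`` is a DataFrame with columns ``t_ms, u_px, v_px[, conf]``
    or an iterable of :class:`Detection`.  Dropout gaps shorter than the
    coast horizon are filled at the nominal frame interval by
    constant-velocity coasting (rows flagged ``interpolated``); longer gaps
    split the track into segments.
    """
    dets = _as_detections(detections)
    if not dets:
        return Track(data=pd.DataFrame(columns=_TRACK_COLUMNS), n_segments=0)
    if any(b.timestamp_ms < a.timestamp_ms for a, b in zip(dets, dets[1:])):
        raise ConfigurationError("detection timestamps must be non-decreasing")
    if frame_interval_ms is None:
        gaps = np.diff([d.timestamp_ms for d in dets])
        frame_interval_ms = float(np.median(gaps)) if len(gaps) else 0.0

    rows: list[tuple] = []
    prev: Localization | None = None
    velocity = 0.0  # mm/s along arc length
    segment = 0
    s_max = milestones[-1].arc_length_s
    for det in dets:
        t0 = time.perf_counter()
        if prev is not None:
            gap = det.timestamp_ms - prev.timestamp_ms
            if gap > coast_horizon_ms:
                segment += 1
                prev = None
                velocity = 0.0
            elif frame_interval_ms > 0 and gap > 1.5 * frame_interval_ms:
                # fill the dropout with constant-velocity coasting
                n_fill = int(round(gap / frame_interval_ms)) - 1
                for k in range(1, n_fill + 1):
                    t_fill = prev.timestamp_ms + k * frame_interval_ms
                    s_fill = float(
                        np.clip(prev.s + velocity * (t_fill - prev.timestamp_ms) / 1e3, 0.0, s_max)
                    )
                    pos = _interp_position(milestones, s_fill)
                    rows.append((t_fill, *pos, s_fill, -1, True, segment, 0.0))
        loc = localize_detection(
            det, cal, milestones, prev=prev, max_speed_mm_s=max_speed_mm_s, mode=mode
        )
        if loc is None:
            # ambiguity: coast on the prediction, flagged as interpolated
            if prev is None:
                continue
            dt_s = (det.timestamp_ms - prev.timestamp_ms) / 1e3
            s_coast = float(np.clip(prev.s + velocity * dt_s, 0.0, s_max))
            pos = _interp_position(milestones, s_coast)
            latency = (time.perf_counter() - t0) * 1e3
            rows.append((det.timestamp_ms, *pos, s_coast, -1, True, segment, latency))
            prev = Localization(pos, s_coast, -1, math.inf, det.timestamp_ms, ambiguous=True)
            continue
        if prev is not None and det.timestamp_ms > prev.timestamp_ms:
            velocity = (loc.s - prev.s) / ((det.timestamp_ms - prev.timestamp_ms) / 1e3)
        latency = (time.perf_counter() - t0) * 1e3
        rows.append(
            (det.timestamp_ms, *loc.position, loc.s, loc.milestone_index, False, segment, latency)
        )
        prev = loc
    frame = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    return Track(data=frame, n_segments=int(frame["segment"].nunique()) if len(frame) else 0)


def _as_detections(detections) -> list[Detection]:
    if isinstance(detections, pd.DataFrame):
        conf = detections["conf"] if "conf" in detections.columns else 1.0
        frame = detections.assign(conf=conf)
        return [
            Detection(row.t_ms, row.u_px, row.v_px, row.conf)
            for row in frame.itertuples(index=False)
        ]
    return [d if isinstance(d, Detection) else Detection(*d) for d in detections]


def track_error_stats(track: Track, truth: pd.DataFrame) -> dict:
    """3D error statistics of a track against simulator ground truth.

    ``truth`` has columns ``t_ms, x_mm, y_mm, z_mm, s_mm``; only
    non-interpolated track samples are scored.
    """
    obs = track.data[~track.data["interpolated"]]
    merged = obs.merge(truth, on="t_ms", suffixes=("", "_true"))
    if merged.empty:
        return {"n": 0}
    err = merged[["x_mm", "y_mm", "z_mm"]].to_numpy() - merged[
        ["x_mm_true", "y_mm_true", "z_mm_true"]
    ].to_numpy()
    d3 = np.linalg.norm(err, axis=1)
    return {
        "n": int(len(merged)),
        "rms_3d_mm": float(np.sqrt(np.mean(d3**2))),
        "max_3d_mm": float(d3.max()),
        "rms_z_mm": float(np.sqrt(np.mean(err[:, 2] ** 2))),
        "max_z_mm": float(np.abs(err[:, 2]).max()),
        "rms_s_mm": float(
            np.sqrt(np.mean((merged["s_mm"] - merged["s_mm_true"]) ** 2))
        ),
        "mean_latency_ms": float(obs["latency_ms"].mean()),
    }
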