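"""Synthetic vessel phantoms, flow waveforms, detection streams and datasets.

Every input the pipeline consumes can be generated here with known ground
truth: the phantom family used on the bench (straight vessels at 0–90°
inclination, a cone tapering 3.6→1.8 mm, a sinusoidal path, a 90°
Y-bifurcation and an arm-scale 3D wrapped path), steady versus pulsatile
flow waveforms, noisy single-view projections of a robot moving along a
centerline, and power-law force–thickness datasets for scaling-law
recovery.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .hemodynamics import FlowCondition
from .localization import FrameCalibration
from .sizing import VesselProfile

PHANTOM_KINDS = ("straight", "tapered", "sinusoidal", "bifurcated", "wrapped3d")

#: Physiologic mean flow-rate range for 1–4 mm vessels under anesthesia, mL/min.
PHYSIOLOGIC_FLOW_RANGE_ML_MIN = (5.0, 150.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom vessel.

    ``diameter`` applies at the start, ``diameter_end`` (if given) at the far
    end with linear interpolation in between; ``length`` is the target arc
    length in mm.
    """

    kind: str = "straight"
    diameter: float = 3.2
    diameter_end: float | None = None
    length: float = 60.0
    inclination_deg: float = 0.0
    amplitude: float = 10.0  # sinusoidal: lateral amplitude, mm
    period: float = 40.0  # sinusoidal: spatial period, mm
    bifurcation_angle_deg: float = 90.0
    wrap_radius: float = 45.0  # wrapped3d: cylinder radius, mm
    wrap_pitch: float = 60.0  # wrapped3d: axial advance per turn, mm
    sample_spacing: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise InvalidSpecError(f"unknown phantom kind {self.kind!r}")
        if self.diameter <= 0 or (self.diameter_end is not None and self.diameter_end <= 0):
            raise InvalidSpecError("diameters must be positive")
        if self.length <= 0:
            raise InvalidSpecError("length must be positive")
        if not self.sample_spacing < self.length / 10:
            raise InvalidSpecError("sample_spacing must be below length/10")
        if self.kind == "tapered" and self.diameter_end is None:
            raise InvalidSpecError("tapered phantoms need diameter_end")


@dataclass(frozen=True)
class BifurcatedProfile:
    """A trunk splitting into two daughters at the configured angle."""

    trunk: VesselProfile
    daughters: tuple[VesselProfile, VesselProfile]

    @property
    def inter_branch_angle_deg(self) -> float:
        dirs = []
        for d in self.daughters:
            v = d.centerline[-1] - d.centerline[0]
            dirs.append(v / np.linalg.norm(v))
        cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
        return math.degrees(math.acos(cosang))


def _radii(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    d_end = spec.diameter if spec.diameter_end is None else spec.diameter_end
    frac = s / s[-1]
    return (spec.diameter + (d_end - spec.diameter) * frac) / 2.0


def make_phantom(spec: PhantomSpec) -> VesselProfile | BifurcatedProfile:
    """Build the phantom centerline + lumen radius for the requested kind."""
    n = int(round(spec.length / spec.sample_spacing)) + 1
    s = np.linspace(0.0, spec.length, n)
    if spec.kind in ("straight", "tapered"):
        th = math.radians(spec.inclination_deg)
        direction = np.array([math.cos(th), 0.0, math.sin(th)])
        pts = s[:, None] * direction
        return VesselProfile(centerline=pts, radius=_radii(spec, s))
    if spec.kind == "sinusoidal":
        return _sinusoidal(spec, s)
    if spec.kind == "wrapped3d":
        # helix on a cylinder: arc length is linear in the turn angle
        c = spec.wrap_pitch / (2 * math.pi)
        rate = 1.0 / math.hypot(spec.wrap_radius, c)  # dθ/ds
        theta = s * rate
        pts = np.column_stack(
            [
                spec.wrap_radius * np.cos(theta),
                spec.wrap_radius * np.sin(theta),
                c * theta,
            ]
        )
        return VesselProfile(centerline=pts, radius=_radii(spec, s))
    return _bifurcated(spec, s)


def _sinusoidal(spec: PhantomSpec, s: np.ndarray) -> VesselProfile:
    # parameterize by x on a fine grid, then resample at uniform arc length
    x_max = spec.length  # generous: arc length >= x extent
    x_fine = np.linspace(0.0, x_max, 40 * len(s))
    y_fine = spec.amplitude * np.sin(2 * math.pi * x_fine / spec.period)
    pts_fine = np.column_stack([x_fine, y_fine, np.zeros_like(x_fine)])
    seg = np.linalg.norm(np.diff(pts_fine, axis=0), axis=1)
    s_fine = np.concatenate([[0.0], np.cumsum(seg)])
    pts = np.column_stack(
        [np.interp(s, s_fine, pts_fine[:, i]) for i in range(3)]
    )
    return VesselProfile(centerline=pts, radius=_radii(spec, s))


def _bifurcated(spec: PhantomSpec, s: np.ndarray) -> BifurcatedProfile:
    half = spec.length / 2.0
    n_half = int(round(half / spec.sample_spacing)) + 1
    s_half = np.linspace(0.0, half, n_half)
    r_half = np.full(n_half, spec.diameter / 2.0)
    trunk = VesselProfile(
        centerline=s_half[:, None] * np.array([1.0, 0.0, 0.0]), radius=r_half
    )
    apex = trunk.centerline[-1]
    half_angle = math.radians(spec.bifurcation_angle_deg / 2.0)
    daughters = []
    for sign in (+1.0, -1.0):
        direction = np.array(
            [math.cos(half_angle), sign * math.sin(half_angle), 0.0]
        )
        pts = apex + s_half[:, None] * direction
        # daughter lumens scale down (symmetric split)
        daughters.append(
            VesselProfile(centerline=pts, radius=0.75 * r_half)
        )
    return BifurcatedProfile(trunk=trunk, daughters=(daughters[0], daughters[1]))


def simulate_flow_waveform(
    flow: FlowCondition,
    duration_s: float = 2.0,
    dt: float = 0.01,
    period_s: float = 1.0,
) -> pd.DataFrame:
    """Time series Q(t): constant for steady, rectified-sine for pulsatile.

    The pulsatile waveform is a half-sine systolic pulse over the systolic
    fraction of each cardiac period on a diastolic baseline; samples are
    rescaled so the discrete time-average equals the requested mean exactly.
    """
    if dt >= period_s / 20:
        raise InvalidSpecError("dt must resolve the cycle (dt < period/20)")
    t = np.arange(0.0, duration_s, dt)
    q_mean = flow.flow_rate_q
    if not flow.pulsatile or q_mean == 0:
        return pd.DataFrame({"t_s": t, "q_ml_min": np.full_like(t, q_mean)})
    fs = flow.systolic_fraction
    ratio = flow.peak_mean_ratio
    q_peak = ratio * q_mean
    # diastolic baseline chosen so the continuous mean equals q_mean
    q_dia = q_mean * (1.0 - fs * ratio * 2.0 / math.pi) / (1.0 - fs)
    if q_dia < 0:
        raise InvalidSpecError(
            "waveform infeasible: peak_mean_ratio too high for the systolic fraction"
        )
    phase = np.mod(t, period_s) / period_s
    q = np.where(
        phase < fs,
        q_peak * np.sin(math.pi * phase / fs),
        q_dia,
    )
    q *= q_mean / q.mean()  # pin the discrete mean exactly
    return pd.DataFrame({"t_s": t, "q_ml_min": q})


def simulate_projection_stream(
    profile: VesselProfile,
    t_ms: np.ndarray,
    s_mm: np.ndarray,
    cal: FrameCalibration,
    noise_px: float = 0.0,
    dropout_prob: float = 0.0,
    occlusion_windows_ms=(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project a known trajectory s(t) into the image plane.

    Returns ``(detections, ground_truth)`` DataFrames.  Detections carry
    Gaussian pixel noise and lose samples to random dropout and to the
    occlusion windows (robot arm / magnet crossing the field of view);
    ground truth keeps every sample for error scoring.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    s_mm = np.asarray(s_mm, dtype=float)
    if t_ms.shape != s_mm.shape:
        raise InvalidSpecError("t_ms and s_mm must have matching shapes")
    if np.any(s_mm < -1e-9) or np.any(s_mm > profile.total_length + 1e-9):
        raise InvalidSpecError("trajectory leaves the centerline extent")
    rng = np.random.default_rng(seed)
    pts = profile.point_at(s_mm)
    inplane = cal.project(pts)
    uv = cal.world_to_image(inplane)
    truth = pd.DataFrame(
        {
            "t_ms": t_ms,
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2],
            "s_mm": s_mm,
        }
    )
    uv_noisy = uv + rng.normal(0.0, noise_px, size=uv.shape) if noise_px > 0 else uv
    keep = rng.random(len(t_ms)) >= dropout_prob
    for lo, hi in occlusion_windows_ms:
        keep &= ~((t_ms >= lo) & (t_ms <= hi))
    detections = pd.DataFrame(
        {
            "t_ms": t_ms[keep],
            "u_px": uv_noisy[keep, 0],
            "v_px": uv_noisy[keep, 1],
            "conf": np.ones(int(keep.sum())),
        }
    )
    return detections, truth


def make_force_thickness_dataset(
    exponent: float = 3.05,
    coeff: float = 1.0,
    t_min: float = 0.1,
    t_max: float = 0.5,
    n: int = 50,
    noise_sigma: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic force–thickness pairs ``c·t^e·exp(N(0, σ))`` for fit recovery."""
    if n < 5:
        raise InvalidSpecError("need at least 5 points")
    if t_min <= 0 or t_max <= t_min:
        raise InvalidSpecError("require 0 < t_min < t_max")
    rng = np.random.default_rng(seed)
    t = np.linspace(t_min, t_max, n)
    noise = rng.normal(0.0, noise_sigma, size=n) if noise_sigma > 0 else np.zeros(n)
    force = coeff * t**exponent * np.exp(noise)
    return pd.DataFrame({"t_mm": t, "force_mN": force})
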