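"""Operational limit rules and catalog-based robot selection for a target vessel.

Two rules govern whether a robot size fits a vessel segment with extreme
lumen diameters ``Dmin``/``Dmax``:

* Rule 1 (continuous wall contact): the robot must carry at least 10% bias
  compressive strain everywhere, i.e. ``Dr ≥ 1.1·Dmax``.
* Rule 2 (deformation ceiling): compressive strain may not exceed 35%,
  i.e. ``Dr ≤ Dmin/0.65``.  The 35% cap is the observed 42% conformal
  deformation limit in tapered phantoms minus a 7% safety margin.

Rule 2 additionally supports a small relative "marginal" tolerance
(default 2%) because measured lumen diameters carry rounding uncertainty;
marginal passes are flagged, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError, InvalidSpecError
from .helix import RobotSpec

#: Observed conformal-deformation limit in tapered phantom runs (strain).
OBSERVED_CONICAL_LIMIT = 0.42

#: Safety margin subtracted from the observed limit (strain).
STRAIN_SAFETY_MARGIN = 0.07

#: Maximum allowed compressive strain (Rule 2 cap).
MAX_STRAIN = OBSERVED_CONICAL_LIMIT - STRAIN_SAFETY_MARGIN

#: Rule 1 multiplier: Dr >= RULE1_MULTIPLIER * Dmax.
RULE1_MULTIPLIER = 1.1

#: Rule 2 denominator: Dr <= Dmin / RULE2_DENOMINATOR.
RULE2_DENOMINATOR = 1.0 - MAX_STRAIN

#: Available fabricated sizes, mm.
DEFAULT_CATALOG = (1.7, 2.1, 2.5, 3.0, 3.6)

_BOUNDARY_EPS = 1e-12  # absorb float noise at exact rule boundaries


@dataclass(frozen=True)
class VesselProfile:
    """Vessel centerline polyline with a lumen radius at every point.

    ``centerline`` is an (N, 3) array of points in mm; ``radius`` the lumen
    radius (mm) at each point.  The cumulative chord length along the
    polyline provides the arc-length coordinate ``s``.
    """

    centerline: np.ndarray
    radius: np.ndarray
    arc_length: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float)
        rad = np.asarray(self.radius, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise InvalidSpecError(
                f"centerline must be an (N>=2, 3) array, got shape {pts.shape}"
            )
        if rad.shape != (pts.shape[0],):
            raise InvalidSpecError("radius must have one value per centerline point")
        if not np.all(rad > 0):
            raise InvalidSpecError("radius must be positive everywhere")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise InvalidSpecError("consecutive centerline points must be distinct")
        s = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "centerline", pts)
        object.__setattr__(self, "radius", rad)
        object.__setattr__(self, "arc_length", s)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def d_min(self) -> float:
        return float(2.0 * self.radius.min())

    @property
    def d_max(self) -> float:
        return float(2.0 * self.radius.max())

    def radius_at(self, s) -> np.ndarray:
        return np.interp(s, self.arc_length, self.radius)

    def point_at(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.stack(
            [np.interp(s, self.arc_length, self.centerline[:, i]) for i in range(3)],
            axis=-1,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_mm": self.arc_length,
                "x_mm": self.centerline[:, 0],
                "y_mm": self.centerline[:, 1],
                "z_mm": self.centerline[:, 2],
                "radius_mm": self.radius,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VesselProfile":
        missing = {"x_mm", "y_mm", "z_mm", "radius_mm"} - set(frame.columns)
        if missing:
            raise InvalidSpecError(f"vessel table missing columns: {sorted(missing)}")
        pts = frame[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        return cls(centerline=pts, radius=frame["radius_mm"].to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "VesselProfile":
        frame = pd.read_csv(path)
        if frame.empty:
            raise InvalidSpecError(f"vessel file {path} contains no points")
        return cls.from_frame(frame)


@dataclass(frozen=True)
class Rule1Check:
    """Wall-contact rule: Dr >= 1.1·Dmax.  margin = Dr/(1.1·Dmax) − 1."""

    passed: bool
    margin: float
    threshold: float


@dataclass(frozen=True)
class Rule2Check:
    """Strain-cap rule: Dr <= Dmin/0.65; 'marginal' within the tolerance."""

    status: str  # 'pass' | 'marginal' | 'fail'
    margin: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.status == "pass"

    @property
    def acceptable(self) -> bool:
        return self.status in ("pass", "marginal")


@dataclass(frozen=True)
class StrainProfile:
    """Compressive strain along the arc length for a given robot size."""

    s: np.ndarray
    strain: np.ndarray
    eps_min: float
    eps_max: float


@dataclass(frozen=True)
class SizingResult:
    chosen_dr: float | None
    rule1: Rule1Check | None
    rule2: Rule2Check | None
    d_bias: float | None
    strain_range: tuple[float, float] | None
    marginal: bool
    diagnostics: tuple[str, ...] = ()


def bias_diameter(dr: float, eps_bias_percent: float) -> float:
    """Preloaded diameter ``Dbias = Dr·(1 − εbias/100)``, mm."""
    if dr <= 0:
        raise InvalidSpecError(f"dr must be positive, got {dr}")
    if not 0 <= eps_bias_percent < 100:
        raise InvalidSpecError(
            f"eps_bias_percent must lie in [0, 100), got {eps_bias_percent}"
        )
    return dr * (1.0 - eps_bias_percent / 100.0)


def check_rule1(dr: float, d_max: float) -> Rule1Check:
    if dr <= 0 or d_max <= 0:
        raise InvalidSpecError("dr and d_max must be positive")
    threshold = RULE1_MULTIPLIER * d_max
    margin = dr / threshold - 1.0
    return Rule1Check(passed=margin >= -_BOUNDARY_EPS, margin=margin, threshold=threshold)


def check_rule2(
    dr: float,
    d_min: float,
    tolerance_rel: float = 0.02,
    denominator: float = RULE2_DENOMINATOR,
) -> Rule2Check:
    if dr <= 0 or d_min <= 0:
        raise InvalidSpecError("dr and d_min must be positive")
    threshold = d_min / denominator
    margin = dr / threshold - 1.0
    if margin <= _BOUNDARY_EPS:
        status = "pass"
    elif margin <= tolerance_rel + _BOUNDARY_EPS:
        status = "marginal"
    else:
        status = "fail"
    return Rule2Check(status=status, margin=margin, threshold=threshold)


def strain_profile(spec: RobotSpec | float, profile: VesselProfile) -> StrainProfile:
    """Compressive strain ε(s) = max(0, (Dr − 2·r(s))/Dr) along the segment."""
    dr = spec.dr if isinstance(spec, RobotSpec) else float(spec)
    strain = np.clip((dr - 2.0 * profile.radius) / dr, 0.0, None)
    return StrainProfile(
        s=profile.arc_length,
        strain=strain,
        eps_min=float(strain.min()),
        eps_max=float(strain.max()),
    )


def select_robot(
    profile: VesselProfile,
    catalog=DEFAULT_CATALOG,
    eps_bias_percent: float = 10.0,
    tolerance_rel: float = 0.02,
) -> SizingResult:
    """Smallest catalog size passing Rule 1 and Rule 2 (or Rule 2 marginal)."""
    return select_robot_for_diameters(
        profile.d_max,
        profile.d_min,
        catalog,
        eps_bias_percent=eps_bias_percent,
        tolerance_rel=tolerance_rel,
        profile=profile,
    )


def select_robot_for_diameters(
    d_max: float,
    d_min: float,
    catalog=DEFAULT_CATALOG,
    eps_bias_percent: float = 10.0,
    tolerance_rel: float = 0.02,
    profile: VesselProfile | None = None,
) -> SizingResult:
    catalog = sorted(catalog)
    if not catalog:
        raise ConfigurationError("robot catalog is empty")
    if d_min > d_max:
        raise GeometryError(f"d_min={d_min} exceeds d_max={d_max}")
    diagnostics: list[str] = []
    for dr in catalog:
        r1 = check_rule1(dr, d_max)
        r2 = check_rule2(dr, d_min, tolerance_rel=tolerance_rel)
        if r1.passed and r2.acceptable:
            if profile is not None:
                sp = strain_profile(dr, profile)
                strain_range = (sp.eps_min, sp.eps_max)
            else:
                strain_range = (
                    max(0.0, (dr - d_max) / dr),
                    max(0.0, (dr - d_min) / dr),
                )
            if r2.status == "marginal":
                diagnostics.append(
                    f"Dr={dr} passes Rule 2 only within the {tolerance_rel:.0%} "
                    f"tolerance (exceedance {r2.margin:.2%})"
                )
            return SizingResult(
                chosen_dr=dr,
                rule1=r1,
                rule2=r2,
                d_bias=bias_diameter(dr, eps_bias_percent),
                strain_range=strain_range,
                marginal=r2.status == "marginal",
                diagnostics=tuple(diagnostics),
            )
        diagnostics.append(
            f"Dr={dr}: rule1 {'pass' if r1.passed else 'fail'} "
            f"(margin {r1.margin:+.2%}), rule2 {r2.status} (margin {r2.margin:+.2%})"
        )
    return SizingResult(
        chosen_dr=None,
        rule1=None,
        rule2=None,
        d_bias=None,
        strain_range=None,
        marginal=False,
        diagnostics=tuple(diagnostics),
    )
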