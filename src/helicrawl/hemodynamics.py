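"""Flow kinematics, drag, stability force balances and magnetic actuation.

Two force balances decide whether a wall-hugging helical robot survives a
given blood flow:

* static stability — the stationary robot does not drift while static
  friction exceeds flow drag:   μs·F_radial ≥ F_drag(Q);
* kinetic stability — the rotating robot still advances while the propulsive
  force exceeds kinetic friction plus drag:  F_prop ≥ μk·F_radial + F_drag(Q).

Drag on the wall-hugging annulus is decomposed into a bluff-body inertial
term evaluated at the upstream superficial velocity and a viscous term from
the Poiseuille pressure drop across the open core.  For pulsatile waveforms
the balances use peak-of-cycle drag; vessel compliance (cyclic dilation at
peak flow) transiently relieves strain, and hence friction, in the kinetic
balance — which is why a deeply compressed robot can tolerate more pulsatile
than steady flow.

The propulsive force available from the rotating field is capped both by the
actuation limit (``propulsion_cap_mn``) and by traction (μs·F_radial): a
screw cannot push harder than its grip on the wall.  The traction cap makes
the kinetic threshold provably no larger than the static one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .errors import GeometryError, InvalidSpecError
from .helix import DEFAULT_WALL_OCCUPANCY, HelixState, core_diameter

#: Default propulsion force cap, mN; calibrated so the steady-flow kinetic
#: threshold ordering between low and high strain matches bench behaviour.
DEFAULT_PROPULSION_CAP_MN = 12.0

#: Actuation field envelope, mT.
MAX_FIELD_MT = 145.0

MU0 = 4e-7 * math.pi


@dataclass(frozen=True)
class FlowCondition:
    """Mean flow rate plus waveform shape of the perfusion.

    ``vessel_compliance`` is the fractional diameter dilation per unit of the
    peak-over-mean flow excess — a lumped surrogate for cyclic vessel
    expansion under pulsatile pressure (0 disables the effect).
    """

    flow_rate_q: float  # mL/min, cycle mean
    waveform: str = "steady"  # 'steady' | 'pulsatile'
    systolic_fraction: float = 0.35
    peak_mean_ratio: float = 3.0
    blood_density: float = 1060.0  # kg/m³
    blood_viscosity: float = 3.5  # mPa·s
    vessel_compliance: float = 0.0

    def __post_init__(self) -> None:
        if self.flow_rate_q < 0:
            raise InvalidSpecError("flow_rate_q must be non-negative")
        if self.waveform not in ("steady", "pulsatile"):
            raise InvalidSpecError(f"unknown waveform {self.waveform!r}")
        if not 0 < self.systolic_fraction < 1:
            raise InvalidSpecError("systolic_fraction must lie in (0, 1)")
        if self.peak_mean_ratio < 1:
            raise InvalidSpecError("peak_mean_ratio must be >= 1")

    @property
    def pulsatile(self) -> bool:
        return self.waveform == "pulsatile"

    @property
    def peak_flow_rate(self) -> float:
        return self.flow_rate_q * (self.peak_mean_ratio if self.pulsatile else 1.0)


@dataclass(frozen=True)
class StabilityParams:
    mu_static: float = 0.30
    mu_kinetic: float = 0.25
    drag_coefficient_cd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mu_kinetic <= self.mu_static:
            raise InvalidSpecError("require 0 < mu_kinetic <= mu_static")
        if self.drag_coefficient_cd <= 0:
            raise InvalidSpecError("drag_coefficient_cd must be positive")


@dataclass(frozen=True)
class CrawlGeometry:
    """Annular flow geometry of a robot hugging a vessel wall (mm)."""

    vessel_diameter: float
    core_diameter: float
    robot_length: float

    def __post_init__(self) -> None:
        if not 0 < self.core_diameter < self.vessel_diameter:
            raise GeometryError(
                "require 0 < core_diameter < vessel_diameter, got "
                f"core={self.core_diameter}, vessel={self.vessel_diameter}"
            )
        if self.robot_length <= 0:
            raise GeometryError("robot_length must be positive")

    @classmethod
    def from_state(
        cls,
        state: HelixState,
        vessel_diameter: float | None = None,
        wall_occupancy: float = DEFAULT_WALL_OCCUPANCY,
    ) -> "CrawlGeometry":
        vd = state.diameter if vessel_diameter is None else vessel_diameter
        return cls(
            vessel_diameter=vd,
            core_diameter=core_diameter(vd, wall_occupancy),
            robot_length=state.length,
        )

    @property
    def lumen_area_mm2(self) -> float:
        return math.pi / 4 * self.vessel_diameter**2

    @property
    def core_area_mm2(self) -> float:
        return math.pi / 4 * self.core_diameter**2

    @property
    def annulus_area_mm2(self) -> float:
        return self.lumen_area_mm2 - self.core_area_mm2


def flow_velocity(q_ml_min: float, core_area_mm2: float) -> float:
    """Mean velocity (cm/s) of flow rate ``q`` through the open core area."""
    if core_area_mm2 <= 0:
        raise GeometryError("core area must be positive")
    return (q_ml_min / 60.0) / (core_area_mm2 / 100.0)


def reynolds_number(
    q_ml_min: float,
    diameter_mm: float,
    density: float = 1060.0,
    viscosity_mpas: float = 3.5,
) -> float:
    area = math.pi / 4 * (diameter_mm * 1e-3) ** 2
    v = q_ml_min * 1e-6 / 60.0 / area
    return density * v * diameter_mm * 1e-3 / (viscosity_mpas * 1e-3)


def wall_shear_stress(
    q_ml_min: float, core_radius_mm: float, viscosity_mpas: float = 3.5
) -> float:
    """Poiseuille wall shear stress ``4·μ·Q/(π·R³)`` on the open core, Pa."""
    if core_radius_mm <= 0:
        raise GeometryError("core radius must be positive")
    re = reynolds_number(q_ml_min, 2 * core_radius_mm, viscosity_mpas=viscosity_mpas)
    if re > 2000:
        warnings.warn(
            f"Reynolds number {re:.0f} exceeds 2000; laminar shear estimate unreliable",
            stacklevel=2,
        )
    q = q_ml_min * 1e-6 / 60.0
    mu = viscosity_mpas * 1e-3
    return 4.0 * mu * q / (math.pi * (core_radius_mm * 1e-3) ** 3)


@dataclass(frozen=True)
class DragResult:
    mean_mn: float
    peak_mn: float


def _drag_at_q(q_ml_min: float, flow: FlowCondition, geom: CrawlGeometry, stab: StabilityParams) -> float:
    q_si = q_ml_min * 1e-6 / 60.0  # m³/s
    lumen = geom.lumen_area_mm2 * 1e-6
    core = geom.core_area_mm2 * 1e-6
    annulus = geom.annulus_area_mm2 * 1e-6
    v_inf = q_si / lumen  # upstream superficial velocity
    inertial = stab.drag_coefficient_cd * 0.5 * flow.blood_density * v_inf**2 * annulus
    v_core = q_si / core
    r_core = geom.core_diameter * 1e-3 / 2.0
    dp = 8.0 * flow.blood_viscosity * 1e-3 * geom.robot_length * 1e-3 * v_core / r_core**2
    viscous = dp * annulus
    return (inertial + viscous) * 1e3  # mN


def drag_force(flow: FlowCondition, geom: CrawlGeometry, stab: StabilityParams | None = None) -> DragResult:
    """Cycle-mean and peak drag on the wall-hugging robot, mN."""
    stab = stab or StabilityParams()
    mean = _drag_at_q(flow.flow_rate_q, flow, geom, stab)
    peak = _drag_at_q(flow.peak_flow_rate, flow, geom, stab) if flow.pulsatile else mean
    return DragResult(mean_mn=mean, peak_mn=peak)


@dataclass(frozen=True)
class StabilityThreshold:
    q_ml_min: float
    capped: bool  # True when the balance holds beyond the evaluation cap


def _solve_q_for_drag(
    budget_mn: float,
    flow: FlowCondition,
    geom: CrawlGeometry,
    stab: StabilityParams,
    q_cap: float,
) -> StabilityThreshold:
    """Largest mean Q (mL/min) with peak-of-cycle drag at or below the budget."""
    if budget_mn <= 0:
        return StabilityThreshold(0.0, capped=False)
    ratio = flow.peak_mean_ratio if flow.pulsatile else 1.0

    def excess(q: float) -> float:
        return _drag_at_q(q * ratio, flow, geom, stab) - budget_mn

    if excess(q_cap) < 0:
        return StabilityThreshold(q_cap, capped=True)
    root = optimize.brentq(excess, 0.0, q_cap, xtol=1e-9)
    return StabilityThreshold(float(root), capped=False)


def static_stability_max_q(
    stab: StabilityParams,
    radial_force_mn: float,
    flow: FlowCondition,
    geom: CrawlGeometry,
    q_cap: float = 2000.0,
) -> StabilityThreshold:
    """Largest mean flow rate the stationary robot endures without drifting."""
    if radial_force_mn < 0:
        raise InvalidSpecError("radial force must be non-negative")
    return _solve_q_for_drag(stab.mu_static * radial_force_mn, flow, geom, stab, q_cap)


def effective_strain(flow: FlowCondition, strain: float) -> float:
    """Strain after pulsatile compliance-driven transient vessel dilation."""
    if not flow.pulsatile or flow.vessel_compliance <= 0:
        return strain
    relief = flow.vessel_compliance * (flow.peak_mean_ratio - 1.0)
    return max(0.0, strain - relief)


def kinetic_stability_max_q(
    stab: StabilityParams,
    radial_force_of_strain,
    strain: float,
    flow: FlowCondition,
    geom: CrawlGeometry,
    propulsion_cap_mn: float = DEFAULT_PROPULSION_CAP_MN,
    q_cap: float = 2000.0,
    tilt_deg: float = 0.0,
    robot_weight_mn: float = 0.0,
) -> StabilityThreshold:
    """Largest mean flow rate against which the rotating robot still advances.

    ``radial_force_of_strain`` maps strain to the radial (normal) force in
    mN, so compliance-driven strain relief under pulsatile flow is applied
    before friction is evaluated.  ``tilt_deg`` adds the submerged-weight
    component along the vessel axis to the resistance for upstream climbs.
    """
    if propulsion_cap_mn < 0:
        raise InvalidSpecError("propulsion_cap_mn must be non-negative")
    eps = effective_strain(flow, strain)
    f_n = float(radial_force_of_strain(eps))
    f_prop = min(propulsion_cap_mn, stab.mu_static * f_n)  # traction-limited
    gravity = robot_weight_mn * math.sin(math.radians(tilt_deg))
    budget = f_prop - stab.mu_kinetic * f_n - gravity
    return _solve_q_for_drag(budget, flow, geom, stab, q_cap)


# --- magnetic actuation -------------------------------------------------------


@dataclass(frozen=True)
class MagnetModel:
    """Robot-arm-mounted permanent magnet approximated as a point dipole."""

    moment: float  # A·m²
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # m
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_frequency_fm: float = 30.0  # Hz
    translation_speed_vm: float = 0.0  # mm/s
    characteristic_radius: float = 0.02  # m

    def __post_init__(self) -> None:
        if self.moment <= 0:
            raise InvalidSpecError("magnet moment must be positive")
        if self.rotation_frequency_fm < 0:
            raise InvalidSpecError("rotation frequency must be non-negative")
        if not 0 <= self.translation_speed_vm <= 5.0:
            raise InvalidSpecError("translation speed must lie in [0, 5] mm/s")
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise InvalidSpecError("magnet axis must be non-zero")
        object.__setattr__(self, "axis", tuple(np.asarray(self.axis, float) / n))

    def field_at(self, point) -> np.ndarray:
        """Dipole field (mT) at a point given in metres."""
        r = np.asarray(point, dtype=float) - np.asarray(self.position, dtype=float)
        return dipole_field(self.moment * np.asarray(self.axis), r, self.characteristic_radius)

    def within_envelope(self, point) -> bool:
        return float(np.linalg.norm(self.field_at(point))) <= MAX_FIELD_MT


def dipole_field(moment_vec, r_vec, min_distance: float = 0.0) -> np.ndarray:
    """Point-dipole magnetic field in mT at displacement ``r_vec`` (metres)."""
    m = np.asarray(moment_vec, dtype=float)
    r = np.asarray(r_vec, dtype=float)
    dist = float(np.linalg.norm(r))
    if dist <= min_distance or dist == 0.0:
        raise GeometryError(
            f"field point distance {dist} m is inside the magnet radius {min_distance} m"
        )
    rhat = r / dist
    b_t = MU0 / (4 * math.pi) * (3 * np.dot(m, rhat) * rhat - m) / dist**3
    return b_t * 1e3


def magnetic_torque_and_pull(robot_moment_vec, field_mt, field_gradient_t_per_m=None):
    """Torque (mN·mm) and pull force (mN) on the robot dipole.

    ``field_gradient_t_per_m[i, j]`` is ∂B_i/∂x_j in T/m; the pull is
    ``F_i = Σ_j m_j ∂B_j/∂x_i`` and vanishes in a uniform field.
    """
    m = np.asarray(robot_moment_vec, dtype=float)
    b = np.asarray(field_mt, dtype=float) * 1e-3
    torque = np.cross(m, b) * 1e6  # N·m -> mN·mm
    if field_gradient_t_per_m is None:
        pull = np.zeros(3)
    else:
        g = np.asarray(field_gradient_t_per_m, dtype=float)
        pull = g.T @ m * 1e3  # N -> mN
    return torque, pull


def corkscrew_velocity(state: HelixState, fm_hz: float, slip_fraction: float = 0.0) -> float:
    """Forward speed of synchronous corkscrew motion: ``λ·fm·(1 − slip)``, mm/s."""
    if fm_hz < 0:
        raise InvalidSpecError("rotation frequency must be non-negative")
    if not 0 <= slip_fraction <= 1:
        raise InvalidSpecError("slip_fraction must lie in [0, 1]")
    return state.pitch * fm_hz * (1.0 - slip_fraction)


def step_out_slip(available_torque_mnmm: float, resisting_torque_mnmm: float) -> float:
    """Slip fraction: zero while torque covers friction, linear ramp beyond.

    Rotation is synchronous while the magnetic torque meets the friction
    torque (μk·F_radial·Dr/2); past step-out the slip grows linearly with
    the torque deficit.
    """
    if available_torque_mnmm < 0 or resisting_torque_mnmm < 0:
        raise InvalidSpecError("torques must be non-negative")
    if resisting_torque_mnmm == 0 or available_torque_mnmm >= resisting_torque_mnmm:
        return 0.0
    return min(1.0, 1.0 - available_torque_mnmm / resisting_torque_mnmm)


def screw_thrust_mn(torque_mnmm: float, lead_mm: float, efficiency: float = 0.1) -> float:
    """Torque-limited screw thrust ``2π·η·τ/λ``, mN; an upper propulsion bound."""
    if lead_mm <= 0:
        raise GeometryError("lead must be positive")
    if not 0 < efficiency <= 1:
        raise InvalidSpecError("efficiency must lie in (0, 1]")
    return 2 * math.pi * efficiency * torque_mnmm / lead_mm
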