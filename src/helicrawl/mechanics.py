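"""Radial force, wall pressure, hysteresis recovery and the wall-thickness scaling law.

The radial force the compressed helix exerts on the lumen splits into an
intrinsic component from stored elastic energy, linear in the compressive
strain and scaling with wall thickness as ``T^3.05``, and an extrinsic
component contributed by the magnetic pulling force (linear in ``T``):

    F_radial = F_intrinsic + F_extrinsic,  F_intrinsic = c0 · (T/T_ref)^3.05 · ε

The absolute force coefficient ``c0`` is calibrated conservatively so that
the largest design strain (ε = 0.40) over the default wall-contact area
produces exactly the 0.75 kPa design pressure ceiling — an order of
magnitude below the ~12.4 kPa pressure tolerance of endothelial cells.

First-cycle hysteresis is modelled by a single recovery ceiling ``r``
(default 0.94): after one load-unload cycle the helix recovers to ``r·Dr``,
so a bias strain ``εbias`` guarantees full recovery over a diameter range of
``(r − (1 − εbias))·100`` percent of ``Dr``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidSpecError
from .helix import RobotSpec, contact_area, derive_nominal_geometry


@dataclass(frozen=True)
class MechanicalParams:
    """Material/force calibration for one robot size.

    ``force_coeff_c0`` is the intrinsic radial force per unit strain (mN) at
    the reference wall thickness ``t_ref`` (mm).  Separate exponents are kept
    for the elastic modulus and the intrinsic force even though both default
    to 3.05.
    """

    t_ref: float
    force_coeff_c0: float
    thickness_exponent: float = 3.05
    modulus_exponent: float = 3.05
    recovery_ratio_r: float = 0.94
    ec_pressure_threshold_kpa: float = 12.4
    pressure_bound_kpa: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "t_ref",
            "force_coeff_c0",
            "thickness_exponent",
            "modulus_exponent",
            "recovery_ratio_r",
            "ec_pressure_threshold_kpa",
            "pressure_bound_kpa",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.recovery_ratio_r > 1:
            raise InvalidSpecError("recovery_ratio_r cannot exceed 1")


#: Design strain at which the calibrated pressure hits the design ceiling.
CALIBRATION_STRAIN = 0.40


def default_mechanical_params(
    spec: RobotSpec, design_strain: float = CALIBRATION_STRAIN
) -> MechanicalParams:
    """Calibrate ``c0`` so pressure(design_strain) equals the design ceiling."""
    nominal = derive_nominal_geometry(spec)
    area = contact_area(nominal, spec.blade_width_b)
    bound = 0.75  # kPa == mN/mm²
    c0 = bound * area / design_strain
    return MechanicalParams(t_ref=spec.wall_thickness_t, force_coeff_c0=c0)


def modulus_scale(t: float, t_ref: float, exponent: float = 3.05) -> float:
    """Stiffness ratio ``(T/T_ref)^exponent`` for a wall thickness change."""
    if t <= 0 or t_ref <= 0:
        raise InvalidSpecError("thicknesses must be positive")
    return (t / t_ref) ** exponent


def intrinsic_radial_force(
    params: MechanicalParams, spec: RobotSpec, strain: float
) -> float:
    """Intrinsic radial force ``c0·(T/T_ref)^3.05·ε``, mN."""
    if not 0 <= strain <= 0.5:
        raise InvalidSpecError(f"strain must lie in [0, 0.5], got {strain}")
    scale = modulus_scale(spec.wall_thickness_t, params.t_ref, params.thickness_exponent)
    return params.force_coeff_c0 * scale * strain


def total_radial_force(f_intrinsic: float, f_extrinsic: float) -> float:
    """F_radial = F_intrinsic + F_extrinsic, mN."""
    if f_intrinsic < 0 or f_extrinsic < 0:
        raise InvalidSpecError("force components must be non-negative")
    return f_intrinsic + f_extrinsic


@dataclass(frozen=True)
class PressureResult:
    kpa: float
    safe: bool  # below the endothelial damage threshold
    design_compliant: bool  # below the design pressure ceiling


def radial_pressure(
    f_radial_mn: float,
    contact_area_mm2: float,
    params: MechanicalParams | None = None,
) -> PressureResult:
    """Contact pressure in kPa (mN/mm² ≡ kPa) with safety verdicts."""
    if contact_area_mm2 <= 0:
        raise InvalidSpecError("contact area must be positive")
    kpa = f_radial_mn / contact_area_mm2
    ec = params.ec_pressure_threshold_kpa if params else 12.4
    bound = params.pressure_bound_kpa if params else 0.75
    return PressureResult(kpa=kpa, safe=kpa <= ec, design_compliant=kpa <= bound)


def recoverable_variation(recovery_ratio_r: float, eps_bias: float) -> float:
    """Diameter variation (percent of Dr) with guaranteed full recovery.

    With a first-cycle recovery ceiling ``r`` and bias strain ``εbias``
    (fraction), the recoverable variation is ``max(0, r − (1 − εbias))·100``.
    """
    if not 0 < recovery_ratio_r <= 1:
        raise InvalidSpecError("recovery_ratio_r must lie in (0, 1]")
    if not 0 <= eps_bias < 1:
        raise InvalidSpecError("eps_bias must lie in [0, 1)")
    return max(0.0, recovery_ratio_r - (1.0 - eps_bias)) * 100.0


def elastic_energy(params: MechanicalParams, spec: RobotSpec, strain: float) -> float:
    """Stored elastic energy ∝ ε²: the integral of the linear force law (mN·strain)."""
    f = intrinsic_radial_force(params, spec, strain)
    return 0.5 * f * strain


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    stderr: float
    log_intercept: float
    r_squared: float


def fit_power_law_exponent(t, response) -> PowerLawFit:
    """Least-squares slope of log(response) vs log(t) with standard error."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(response, dtype=float)
    if t.size < 5 or y.size != t.size:
        raise InvalidSpecError("need at least 5 matched (t, response) pairs")
    if np.any(t <= 0) or np.any(y <= 0):
        raise InvalidSpecError("power-law fit requires strictly positive data")
    res = stats.linregress(np.log(t), np.log(y))
    return PowerLawFit(
        exponent=float(res.slope),
        stderr=float(res.stderr),
        log_intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
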