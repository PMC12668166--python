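"""Helical robot geometry and its deformation kinematics under radial confinement.

The robot is a thin-walled, hollow, magnetic helix that crawls along the
vessel wall while blood flows through its open core.  Its as-fabricated
(nominal) shape is fixed by the outer diameter ``Dr`` together with two
dimensionless ratios: the length ratio ``L/Dr`` (default 3.3, kept above the
anti-tumbling floor of 3.0) and the turn count ``L/λ`` (default 4.8).  When
the vessel lumen is narrower than ``Dr`` the helix is compressed radially and
elongates axially; the helical filament itself is effectively inextensible,
so the deformed turn count follows from conservation of the filament arc
length.  That single conservation law reproduces the observed adaptation of
the turn count from 4.8 up to ~6.7 when the diameter drops to 0.65·Dr and the
length stretches to 7.0·Dr.

Units: millimetres throughout; areas in mm²; strains dimensionless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import GeometryError, InvalidSpecError

#: Default axial blade coverage of one pitch (blade width b = coverage · λ).
DEFAULT_BLADE_COVERAGE = 0.7

#: Default radial wall thickness as a fraction of the nominal diameter.
DEFAULT_WALL_FRACTION = 0.08

#: Default helix lead angle in degrees (held constant across sizes).
DEFAULT_HELIX_ANGLE_DEG = 12.3

#: Effective magnetization of the magnetic elastomer composite, A/m.
COMPOSITE_MAGNETIZATION = 5.0e4

#: Density of the magnetic elastomer composite, kg/m³ (4:1 powder:elastomer).
COMPOSITE_DENSITY = 3.3e3

#: Default fraction of the vessel diameter occupied by the wall-hugging
#: helix on each side, calibrated from printed flow-rate/velocity pairs.
DEFAULT_WALL_OCCUPANCY = 0.19


@dataclass(frozen=True)
class RobotSpec:
    """Nominal (as-fabricated) parameters of one robot size.

    Parameters
    ----------
    dr
        Nominal outer diameter, mm.
    l_over_dr
        Nominal length ratio L/Dr; must stay at or above the 3.0
        anti-tumbling floor.
    n_turns
        Nominal turn count L/λ.
    blade_width_b
        Axial width of the helical blade, mm.  Defaults to 0.7·λ.
    groove_beta
        Axial groove width, mm.  Defaults to λ − b; must stay below the
        blade width (high b/β maximizes wall contact).
    wall_thickness_t
        Radial wall thickness, mm.  Defaults to 0.08·Dr; must stay below
        Dr/4.
    helix_angle_phi
        Helix lead angle, degrees (not scaled with Dr).
    ndfeb_mass_ratio
        Magnetic powder : elastomer mass ratio.
    magnetic_moment
        Dipole moment magnitude, A·m².  Defaults to the composite
        magnetization times the material volume.
    """

    dr: float
    l_over_dr: float = 3.3
    n_turns: float = 4.8
    blade_width_b: float | None = None
    groove_beta: float | None = None
    wall_thickness_t: float | None = None
    helix_angle_phi: float = DEFAULT_HELIX_ANGLE_DEG
    ndfeb_mass_ratio: float = 4.0
    magnetic_moment: float | None = None

    def __post_init__(self) -> None:
        if not self.dr > 0:
            raise InvalidSpecError(f"dr must be positive, got {self.dr}")
        if self.l_over_dr < 3.0:
            raise InvalidSpecError(
                f"l_over_dr must be >= 3.0 (anti-tumbling floor), got {self.l_over_dr}"
            )
        if not self.n_turns > 1:
            raise InvalidSpecError(f"n_turns must exceed 1, got {self.n_turns}")
        pitch = self.nominal_pitch
        if self.blade_width_b is None:
            object.__setattr__(self, "blade_width_b", DEFAULT_BLADE_COVERAGE * pitch)
        if self.groove_beta is None:
            object.__setattr__(self, "groove_beta", pitch - self.blade_width_b)
        if self.wall_thickness_t is None:
            object.__setattr__(self, "wall_thickness_t", DEFAULT_WALL_FRACTION * self.dr)
        if not self.blade_width_b > self.groove_beta:
            raise InvalidSpecError(
                "blade_width_b must exceed groove_beta (high b/β design), got "
                f"b={self.blade_width_b}, beta={self.groove_beta}"
            )
        if not 0 < self.wall_thickness_t < self.dr / 4:
            raise InvalidSpecError(
                f"wall_thickness_t must lie in (0, dr/4), got {self.wall_thickness_t}"
            )
        if self.ndfeb_mass_ratio <= 0:
            raise InvalidSpecError(
                f"ndfeb_mass_ratio must be positive, got {self.ndfeb_mass_ratio}"
            )
        if self.magnetic_moment is None:
            object.__setattr__(
                self,
                "magnetic_moment",
                COMPOSITE_MAGNETIZATION * self.material_volume * 1e-9,
            )

    @property
    def nominal_length(self) -> float:
        """Nominal axial length L = (L/Dr)·Dr, mm."""
        return self.l_over_dr * self.dr

    @property
    def nominal_pitch(self) -> float:
        """Nominal pitch λ = L/(L/λ), mm."""
        return self.nominal_length / self.n_turns

    @property
    def nominal_filament_length(self) -> float:
        """Arc length of the helical filament in the nominal state, mm."""
        return helix_arc_length(self.dr, self.nominal_pitch, self.n_turns)

    @property
    def material_volume(self) -> float:
        """Approximate material volume (filament × blade cross-section), mm³."""
        return self.nominal_filament_length * self.blade_width_b * self.wall_thickness_t

    @property
    def mass_g(self) -> float:
        """Approximate robot mass, grams."""
        return self.material_volume * 1e-3 * COMPOSITE_DENSITY * 1e-3

    def submerged_weight_mn(self, fluid_density: float = 1060.0) -> float:
        """Weight minus buoyancy in a fluid of the given density, mN."""
        rho = COMPOSITE_DENSITY - fluid_density
        return rho * self.material_volume * 1e-9 * 9.81 * 1e3


@dataclass(frozen=True)
class HelixState:
    """Instantaneous deformed configuration of the helix.

    ``pitch · turns == length`` holds exactly, and ``filament_length`` is
    conserved (relative to the nominal state) to 1e-6 under any feasible
    deformation produced by :func:`compressed_state`.
    """

    diameter: float
    length: float
    turns: float
    pitch: float
    filament_length: float
    strain: float


def helix_arc_length(diameter: float, pitch: float, turns: float) -> float:
    """Arc length of ``turns`` helical turns on a cylinder, mm.

    ``S = N · sqrt((π·D)² + λ²)``.  ``turns`` may be zero (degenerate helix);
    diameter and pitch must be positive.
    """
    if diameter <= 0 or pitch <= 0:
        raise GeometryError(
            f"diameter and pitch must be positive, got d={diameter}, pitch={pitch}"
        )
    if turns < 0:
        raise GeometryError(f"turns must be non-negative, got {turns}")
    return turns * math.hypot(math.pi * diameter, pitch)


def _effective_diameter(spec: RobotSpec, diameter: float, use_centerline: bool) -> float:
    # Modelling the filament on the outer cylinder reproduces the printed
    # 4.8 -> 6.7 turn adaptation to <1%; the wall-centerline option is kept
    # as a flag for sensitivity studies.
    return diameter - spec.wall_thickness_t if use_centerline else diameter


def derive_nominal_geometry(spec: RobotSpec, use_centerline: bool = False) -> HelixState:
    """Nominal (zero-strain) helix state implied by a :class:`RobotSpec`."""
    length = spec.nominal_length
    pitch = spec.nominal_pitch
    d_eff = _effective_diameter(spec, spec.dr, use_centerline)
    filament = helix_arc_length(d_eff, pitch, spec.n_turns)
    return HelixState(
        diameter=spec.dr,
        length=length,
        turns=spec.n_turns,
        pitch=pitch,
        filament_length=filament,
        strain=0.0,
    )


def compressed_state(
    spec: RobotSpec,
    new_diameter: float,
    new_length: float,
    use_centerline: bool = False,
) -> HelixState:
    """Deformed helix state under radial confinement, conserving filament length.

    The inextensible filament of nominal arc length ``S`` redistributes into
    new conformal turns: ``N' = sqrt(S² − L'²) / (π·D')``.

    Raises
    ------
    GeometryError
        If ``new_length >= S`` (the filament cannot be stretched straight) or
        ``new_diameter`` falls outside ``(0, Dr]``.

    Warns when the implied turn count drops below the nominal count while the
    helix is radially compressed — a non-physical elongation regime.
    """
    if not 0 < new_diameter <= spec.dr:
        raise GeometryError(
            f"new_diameter must lie in (0, Dr={spec.dr}], got {new_diameter}"
        )
    if new_length <= 0:
        raise GeometryError(f"new_length must be positive, got {new_length}")
    nominal = derive_nominal_geometry(spec, use_centerline=use_centerline)
    s = nominal.filament_length
    if new_length >= s:
        raise GeometryError(
            f"new_length={new_length} mm reaches the filament length {s:.4f} mm; "
            "the helix cannot be stretched straight"
        )
    d_eff = _effective_diameter(spec, new_diameter, use_centerline)
    turns = math.sqrt(s * s - new_length * new_length) / (math.pi * d_eff)
    if new_diameter < spec.dr and turns < spec.n_turns:
        warnings.warn(
            "turn count dropped below nominal under radial compression "
            f"({turns:.3f} < {spec.n_turns}); non-physical elongation",
            stacklevel=2,
        )
    pitch = new_length / turns
    return HelixState(
        diameter=new_diameter,
        length=new_length,
        turns=turns,
        pitch=pitch,
        filament_length=helix_arc_length(d_eff, pitch, turns),
        strain=strain_of(spec, new_diameter),
    )


def strain_of(spec: RobotSpec, diameter: float, allow_expansion: bool = False) -> float:
    """Compressive strain ε = (Dr − D)/Dr relative to the as-fabricated diameter."""
    if diameter <= 0:
        raise GeometryError(f"diameter must be positive, got {diameter}")
    if diameter > spec.dr and not allow_expansion:
        raise GeometryError(
            f"diameter {diameter} exceeds Dr={spec.dr} (negative strain); "
            "pass allow_expansion=True to permit it"
        )
    return (spec.dr - diameter) / spec.dr


def contact_area(state: HelixState, blade_width: float) -> float:
    """Outer blade strip area in contact with the vessel wall, mm².

    The strip runs the full filament length with the axial blade width, so
    the area is simply ``b · S``; ``b`` may not exceed the local pitch.
    """
    if blade_width < 0:
        raise GeometryError(f"blade_width must be non-negative, got {blade_width}")
    if blade_width > state.pitch:
        raise GeometryError(
            f"blade_width {blade_width} exceeds the pitch {state.pitch}"
        )
    return blade_width * state.filament_length


def core_diameter(vessel_diameter: float, wall_occupancy_fraction: float = DEFAULT_WALL_OCCUPANCY) -> float:
    """Diameter of the open flow core left by the wall-hugging helix, mm."""
    if vessel_diameter <= 0:
        raise GeometryError(f"vessel_diameter must be positive, got {vessel_diameter}")
    if not 0 < wall_occupancy_fraction < 0.5:
        raise GeometryError(
            f"wall_occupancy_fraction must lie in (0, 0.5), got {wall_occupancy_fraction}"
        )
    return vessel_diameter * (1.0 - 2.0 * wall_occupancy_fraction)


def open_core_area(
    vessel_diameter: float, wall_occupancy_fraction: float = DEFAULT_WALL_OCCUPANCY
) -> float:
    """Cross-sectional area of the open flow core, mm²."""
    d = core_diameter(vessel_diameter, wall_occupancy_fraction)
    return math.pi / 4.0 * d * d
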