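"""Flow kinematics, drag, stability balances, dipole actuation, corkscrew speed."""

import math

import numpy as np
import pytest

from helicrawl import (
    CrawlGeometry,
    FlowCondition,
    StabilityParams,
    corkscrew_velocity,
    derive_nominal_geometry,
    dipole_field,
    drag_force,
    flow_velocity,
    intrinsic_radial_force,
    kinetic_stability_max_q,
    magnetic_torque_and_pull,
    static_stability_max_q,
    wall_shear_stress,
)
from helicrawl.errors import GeometryError, InvalidSpecError
from helicrawl.hemodynamics import (
    MagnetModel,
    _drag_at_q,
    screw_thrust_mn,
    step_out_slip,
)
from helicrawl.mechanics import default_mechanical_params


@pytest.mark.parametrize(
    "q, area, expected",
    [(120, 3.33, 60.1), (150, 1.61, 155.3), (0, 2.0, 0.0)],
)
def test_flow_velocity_through_open_core(q, area, expected):
    assert flow_velocity(q, area) == pytest.approx(expected, abs=0.1)


class TestWallShear:
    def test_poiseuille_estimate(self):
        assert wall_shear_stress(120, 1.03) == pytest.approx(8.16, abs=0.02)

    def test_zero_flow(self):
        assert wall_shear_stress(0, 1.0) == 0.0

    def test_cubic_radius_law(self):
        assert wall_shear_stress(30, 0.5) == pytest.approx(
            8 * wall_shear_stress(30, 1.0), rel=1e-12
        )

    def test_turbulent_regime_warns(self):
        with pytest.warns(UserWarning, match="Reynolds"):
            wall_shear_stress(2000, 1.0)


def _geometry(eb36, strain):
    nominal = derive_nominal_geometry(eb36)
    return CrawlGeometry.from_state(nominal, eb36.dr * (1 - strain))


def _force_fn(eb36):
    mech = default_mechanical_params(eb36)
    return lambda eps: intrinsic_radial_force(mech, eb36, eps)


class TestDrag:
    def test_zero_flow_zero_drag(self, eb36):
        geom = _geometry(eb36, 0.10)
        assert drag_force(FlowCondition(0.0), geom).mean_mn == 0.0

    def test_inertial_term_quadratic(self, eb36):
        geom = _geometry(eb36, 0.10)
        inviscid = FlowCondition(100.0, blood_viscosity=1e-12)
        d1 = drag_force(inviscid, geom).mean_mn
        d2 = drag_force(FlowCondition(200.0, blood_viscosity=1e-12), geom).mean_mn
        assert d2 == pytest.approx(4 * d1, rel=1e-6)

    def test_pulsatile_peak_drag_is_ninefold_inertial(self, eb36):
        geom = _geometry(eb36, 0.10)
        flow = FlowCondition(
            100.0, waveform="pulsatile", peak_mean_ratio=3.0, blood_viscosity=1e-12
        )
        res = drag_force(flow, geom)
        assert res.peak_mn == pytest.approx(9 * res.mean_mn, rel=1e-6)

    def test_monotone_in_flow_rate(self, eb36):
        geom = _geometry(eb36, 0.35)
        drags = [drag_force(FlowCondition(q), geom).mean_mn for q in (10, 50, 100, 200)]
        assert drags == sorted(drags)


class TestStaticStability:
    def test_no_contact_no_stability(self, eb36):
        th = static_stability_max_q(StabilityParams(), 0.0, FlowCondition(1.0), _geometry(eb36, 0.10))
        assert th.q_ml_min == 0.0

    def test_deeper_compression_holds_more_steady_flow(self, eb36):
        """Friction grows faster with strain than annulus drag: the 35%-strain
        deployment out-holds the 10% one under steady flow."""
        f = _force_fn(eb36)
        stab = StabilityParams()
        q10 = static_stability_max_q(stab, f(0.10), FlowCondition(1.0), _geometry(eb36, 0.10))
        q35 = static_stability_max_q(stab, f(0.35), FlowCondition(1.0), _geometry(eb36, 0.35))
        assert q35.q_ml_min > q10.q_ml_min > 0

    def test_root_finder_matches_grid_search(self, eb36):
        f = _force_fn(eb36)
        stab = StabilityParams()
        geom = _geometry(eb36, 0.10)
        flow = FlowCondition(1.0)
        th = static_stability_max_q(stab, f(0.10), flow, geom)
        friction = stab.mu_static * f(0.10)
        grid = 0.0
        for q in np.arange(0.0, 2000.0, 0.25):
            if _drag_at_q(q, flow, geom, stab) <= friction:
                grid = q
        assert abs(th.q_ml_min - grid) <= 1.0

    def test_pulsatile_peak_threshold_below_steady(self, eb36):
        f = _force_fn(eb36)
        stab = StabilityParams()
        geom = _geometry(eb36, 0.10)
        steady = static_stability_max_q(stab, f(0.10), FlowCondition(1.0), geom)
        puls = static_stability_max_q(
            stab, f(0.10), FlowCondition(1.0, waveform="pulsatile"), geom
        )
        assert puls.q_ml_min <= steady.q_ml_min

    def test_cap_reported(self, eb36):
        th = static_stability_max_q(
            StabilityParams(), 1e6, FlowCondition(1.0), _geometry(eb36, 0.10), q_cap=150.0
        )
        assert th.capped and th.q_ml_min == 150.0


class TestKineticStability:
    def test_no_propulsion_no_motion(self, eb36):
        th = kinetic_stability_max_q(
            StabilityParams(), _force_fn(eb36), 0.10, FlowCondition(1.0),
            _geometry(eb36, 0.10), propulsion_cap_mn=0.0,
        )
        assert th.q_ml_min == 0.0

    @pytest.mark.parametrize("strain", [0.10, 0.35])
    @pytest.mark.parametrize("waveform", ["steady", "pulsatile"])
    def test_kinetic_never_exceeds_static(self, eb36, strain, waveform):
        """Propulsion is traction-limited, so advancing is always harder than
        merely holding position."""
        f = _force_fn(eb36)
        stab = StabilityParams()
        geom = _geometry(eb36, strain)
        flow = FlowCondition(1.0, waveform=waveform)
        static = static_stability_max_q(stab, f(strain), flow, geom)
        kinetic = kinetic_stability_max_q(stab, f, strain, flow, geom)
        assert kinetic.q_ml_min <= static.q_ml_min

    def test_steady_flow_low_strain_navigates_more(self, eb36):
        """Under steady flow the lightly compressed robot keeps more of its
        propulsive budget: kinetic threshold at 10% strain exceeds 35%."""
        f = _force_fn(eb36)
        stab = StabilityParams()
        k10 = kinetic_stability_max_q(stab, f, 0.10, FlowCondition(1.0), _geometry(eb36, 0.10))
        k35 = kinetic_stability_max_q(stab, f, 0.35, FlowCondition(1.0), _geometry(eb36, 0.35))
        assert k10.q_ml_min > k35.q_ml_min

    def test_pulsatile_compliance_rescues_deep_compression(self, eb36):
        """Cyclic vessel dilation relieves friction at peak flow, letting the
        35%-strain robot beat its steady-flow threshold."""
        f = _force_fn(eb36)
        stab = StabilityParams()
        geom = _geometry(eb36, 0.35)
        steady = kinetic_stability_max_q(stab, f, 0.35, FlowCondition(1.0), geom)
        puls = kinetic_stability_max_q(
            stab, f, 0.35,
            FlowCondition(1.0, waveform="pulsatile", vessel_compliance=0.1),
            geom,
        )
        assert puls.q_ml_min > steady.q_ml_min

    def test_upstream_threshold_non_increasing_with_tilt(self, eb36):
        f = _force_fn(eb36)
        stab = StabilityParams()
        geom = _geometry(eb36, 0.10)
        weight = eb36.submerged_weight_mn()
        thresholds = [
            kinetic_stability_max_q(
                stab, f, 0.10, FlowCondition(1.0), geom,
                tilt_deg=tilt, robot_weight_mn=weight,
            ).q_ml_min
            for tilt in (0, 30, 60, 90)
        ]
        assert thresholds == sorted(thresholds, reverse=True)


class TestMagnetics:
    def test_axial_dipole_field(self):
        b = dipole_field([0, 0, 1.0], [0, 0, 0.1])
        assert np.linalg.norm(b) == pytest.approx(0.2, rel=1e-9)  # mT

    def test_inverse_cube_falloff(self):
        b1 = np.linalg.norm(dipole_field([0, 0, 1.0], [0, 0, 0.1]))
        b2 = np.linalg.norm(dipole_field([0, 0, 1.0], [0, 0, 0.2]))
        assert b2 == pytest.approx(b1 / 8, rel=1e-9)

    def test_equatorial_field_half_axial(self):
        ax = np.linalg.norm(dipole_field([0, 0, 1.0], [0, 0, 0.1]))
        eq = np.linalg.norm(dipole_field([0, 0, 1.0], [0.1, 0, 0]))
        assert eq == pytest.approx(ax / 2, rel=1e-9)

    def test_inside_magnet_rejected(self):
        with pytest.raises(GeometryError):
            dipole_field([0, 0, 1.0], [0, 0, 0.01], min_distance=0.02)

    def test_parallel_moment_no_torque(self):
        torque, _ = magnetic_torque_and_pull([0, 0, 1e-3], [0, 0, 10.0])
        assert np.allclose(torque, 0.0)

    def test_perpendicular_torque_magnitude(self):
        torque, _ = magnetic_torque_and_pull([1e-3, 0, 0], [0, 0, 10.0])
        # |m||B| = 1e-3·0.01 = 1e-5 N·m = 10 µN·m = 10 mN·mm
        assert np.linalg.norm(torque) == pytest.approx(10.0, rel=1e-9)

    def test_uniform_field_no_pull(self):
        _, pull = magnetic_torque_and_pull([1e-3, 0, 0], [0, 0, 10.0], np.zeros((3, 3)))
        assert np.allclose(pull, 0.0)

    def test_magnet_model_envelope(self):
        magnet = MagnetModel(moment=50.0, position=(0, 0, 0), axis=(0, 0, 1))
        assert magnet.within_envelope((0, 0, 0.15))
        assert not magnet.within_envelope((0, 0, 0.035))


class TestCorkscrew:
    def test_no_slip_speed(self, eb36):
        state = derive_nominal_geometry(eb36)
        assert corkscrew_velocity(state, 10.0) == pytest.approx(24.75)

    def test_full_slip_stalls(self, eb36):
        state = derive_nominal_geometry(eb36)
        assert corkscrew_velocity(state, 10.0, 1.0) == 0.0

    def test_measured_speed_implies_76pct_slip(self, eb36):
        state = derive_nominal_geometry(eb36)
        slip = 1 - 5.9 / (state.pitch * 10.0)
        assert slip == pytest.approx(0.76, abs=0.01)
        assert corkscrew_velocity(state, 10.0, slip) == pytest.approx(5.9, rel=1e-9)

    def test_step_out_ramp(self):
        assert step_out_slip(10.0, 5.0) == 0.0  # synchronous
        assert step_out_slip(5.0, 10.0) == pytest.approx(0.5)
        assert step_out_slip(0.0, 10.0) == 1.0

    def test_screw_thrust_scaling(self):
        assert screw_thrust_mn(100.0, 2.475, efficiency=0.1) == pytest.approx(
            2 * math.pi * 0.1 * 100.0 / 2.475
        )


def test_flow_condition_validation():
    with pytest.raises(InvalidSpecError):
        FlowCondition(-1.0)
    with pytest.raises(InvalidSpecError):
        FlowCondition(10.0, waveform="sawtooth")
    with pytest.raises(InvalidSpecError):
        StabilityParams(mu_static=0.2, mu_kinetic=0.3)
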