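"""Milestone placement, frame calibration, and 2D->3D localization/tracking."""

import numpy as np
import pytest

from helicrawl import (
    Detection,
    FrameCalibration,
    RobotSpec,
    VesselProfile,
    calibrate_frames,
    localize_detection,
    place_milestones,
    track_stream,
)
from helicrawl.errors import CalibrationError, ConfigurationError, GeometryError
from helicrawl.localization import Milestone, track_error_stats
from helicrawl.phantoms import PhantomSpec, make_phantom, simulate_projection_stream

from conftest import straight_vessel


class TestMilestones:
    def test_quarter_length_spacing_on_60mm_vessel(self):
        vessel = straight_vessel(3.0, 3.0, length=60.0)
        milestones = place_milestones(vessel, robot_length=12.0)
        assert len(milestones) == 21
        gaps = np.diff([m.arc_length_s for m in milestones])
        assert np.allclose(gaps, 3.0, atol=1e-9)

    def test_minimal_vessel_gets_endpoints(self):
        vessel = straight_vessel(3.0, 3.0, length=3.0, n=16)
        milestones = place_milestones(vessel, robot_length=12.0)
        assert len(milestones) == 2
        assert milestones[0].arc_length_s == 0.0
        assert milestones[-1].arc_length_s == pytest.approx(3.0)

    def test_uniform_gaps_when_length_not_divisible(self):
        vessel = straight_vessel(3.0, 3.0, length=61.0)
        milestones = place_milestones(vessel, robot_length=12.0)
        gaps = np.diff([m.arc_length_s for m in milestones])
        assert np.ptp(gaps) < 1e-9
        assert gaps[0] <= 3.0 + 1e-9

    def test_degenerate_inputs(self):
        vessel = straight_vessel(3.0, 3.0)
        with pytest.raises(GeometryError):
            place_milestones(vessel, robot_length=0.0)


class TestCalibration:
    def test_identity_fiducials(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        cal, rms = calibrate_frames(pts, pts)
        assert cal.scale == pytest.approx(1.0, abs=1e-12)
        assert cal.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert rms < 1e-9

    def test_pure_scale(self):
        pts = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 7.0]])
        cal, _ = calibrate_frames(pts, 2.0 * pts)
        assert cal.scale == pytest.approx(2.0, abs=1e-12)

    def test_noisy_similarity_recovery(self):
        rng = np.random.default_rng(11)
        true = FrameCalibration(scale=0.42, rotation_deg=17.0, translation=(3.0, -2.0))
        uv = rng.uniform(0, 500, size=(10, 2))
        world = true.image_to_world(uv) + rng.normal(0, 0.1 * 0.42, size=(10, 2))
        cal, rms = calibrate_frames(uv, world)
        assert cal.scale == pytest.approx(0.42, abs=0.005)
        assert cal.rotation_deg == pytest.approx(17.0, abs=0.5)
        assert rms < 0.2

    def test_coincident_fiducials_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(CalibrationError):
            calibrate_frames(pts, pts)

    def test_round_trip_inverse(self):
        cal = FrameCalibration(scale=0.3, rotation_deg=25.0, translation=(1.0, 2.0))
        uv = np.array([[12.0, 34.0], [-5.0, 8.0]])
        np.testing.assert_allclose(cal.world_to_image(cal.image_to_world(uv)), uv, atol=1e-9)


def _milestone(idx, pos, s):
    return Milestone(index=idx, position=np.asarray(pos, float), arc_length_s=s, radius=1.5)


class TestLocalize:
    def test_single_milestone_supplies_depth(self):
        cal = FrameCalibration.identity()
        loc = localize_detection(
            Detection(0.0, 0.1, 0.0), cal, [_milestone(0, [0, 0, 5.0], 0.0)]
        )
        assert loc.position[2] == 5.0
        assert loc.position[0] == pytest.approx(0.1)

    def test_midpoint_interpolates_arc_length_and_depth(self):
        cal = FrameCalibration.identity()
        milestones = [
            _milestone(0, [0, 0, 0.0], 0.0),
            _milestone(1, [3, 0, 1.0], 3.0),
            _milestone(2, [6, 0, 2.0], 6.0),
        ]
        loc = localize_detection(Detection(0.0, 4.5, 0.0), cal, milestones)
        assert loc.s == pytest.approx(4.5)
        assert loc.position[2] == pytest.approx(1.5)

    def test_snap_mode_quantizes_depth(self):
        cal = FrameCalibration.identity()
        milestones = [
            _milestone(0, [0, 0, 0.0], 0.0),
            _milestone(1, [3, 0, 1.0], 3.0),
        ]
        loc = localize_detection(Detection(0.0, 2.0, 0.0), cal, milestones, mode="snap")
        assert loc.position[2] == 1.0  # nearest milestone depth

    def test_hairpin_disambiguated_by_continuity_gate(self):
        """Two overlapping limbs in projection: without history the nearest
        limb wins; with history on the far limb the gate keeps the track there."""
        cal = FrameCalibration.identity()
        near = [_milestone(i, [10 * i, 0.0, 0.0], 10.0 * i) for i in range(4)]
        far = [
            _milestone(4 + i, [30 - 10 * i, 1.0, 20.0], 40.0 + 10.0 * i)
            for i in range(4)
        ]
        milestones = near + far
        det = Detection(1000.0, 15.0, 0.4)  # closer to the near limb (y=0)
        loc_free = localize_detection(det, cal, milestones)
        assert loc_free.s <= 30.0
        prev = localize_detection(Detection(0.0, 16.0, 1.0), cal, milestones, prev=None)
        assert prev.s > 40.0  # seeded on the far limb
        loc_gated = localize_detection(
            det, cal, milestones, prev=prev, max_speed_mm_s=6.0
        )
        assert loc_gated.s > 40.0

    def test_gate_exhaustion_returns_none(self):
        cal = FrameCalibration.identity()
        milestones = [_milestone(0, [0, 0, 0], 0.0), _milestone(1, [30, 0, 0], 30.0)]
        prev = localize_detection(Detection(0.0, 0.0, 0.0), cal, milestones)
        loc = localize_detection(
            Detection(100.0, 30.0, 0.0), cal, milestones, prev=prev, max_speed_mm_s=1.0
        )
        assert loc is None

    def test_empty_milestones_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            localize_detection(Detection(0, 0, 0), FrameCalibration.identity(), [])


def _demo_setup(noise_px=0.0, dropout=0.0, seed=0, speed=5.0):
    phantom = make_phantom(
        PhantomSpec(kind="straight", diameter=2.4, length=60.0, inclination_deg=30.0)
    )
    cal = FrameCalibration(scale=0.1, rotation_deg=0.0, translation=(0.0, 0.0))
    milestones = place_milestones(phantom, RobotSpec(dr=2.1).nominal_length)
    t_ms = np.arange(0.0, 60.0 / speed * 1e3, 66.7)
    s_mm = np.clip(speed * t_ms / 1e3, 0, phantom.total_length)
    dets, truth = simulate_projection_stream(
        phantom, t_ms, s_mm, cal, noise_px=noise_px, dropout_prob=dropout, seed=seed
    )
    return dets, truth, cal, milestones


class TestTrackStream:
    def test_noiseless_traversal_bounded_depth_error(self):
        dets, truth, cal, milestones = _demo_setup()
        track = track_stream(dets, cal, milestones, max_speed_mm_s=15.0)
        stats = track_error_stats(track, truth)
        spacing = milestones[1].arc_length_s - milestones[0].arc_length_s
        assert stats["max_z_mm"] <= spacing / 2
        assert stats["rms_3d_mm"] < spacing

    def test_monotone_arc_length_under_gating(self):
        dets, truth, cal, milestones = _demo_setup(noise_px=1.0, seed=3)
        track = track_stream(dets, cal, milestones, max_speed_mm_s=15.0)
        s = track.data.loc[~track.data["interpolated"], "s_mm"].to_numpy()
        assert np.all(np.diff(s) >= -0.5)  # no backward jumps beyond noise scale

    def test_dropout_gaps_flagged_not_split(self):
        dets, truth, cal, milestones = _demo_setup(dropout=0.10, seed=5)
        track = track_stream(dets, cal, milestones, max_speed_mm_s=15.0, coast_horizon_ms=500.0)
        assert track.n_segments == 1
        assert track.data["interpolated"].any()
        # interpolated rows only appear inside dropout gaps
        filled = track.data[track.data["interpolated"]]
        assert (filled["milestone"] == -1).all()

    def test_long_gap_splits_track(self):
        dets, truth, cal, milestones = _demo_setup()
        gap_start = dets["t_ms"].iloc[len(dets) // 2]
        dets = dets[(dets["t_ms"] < gap_start) | (dets["t_ms"] > gap_start + 900)]
        track = track_stream(dets, cal, milestones, max_speed_mm_s=15.0, coast_horizon_ms=500.0)
        assert track.n_segments == 2

    def test_empty_stream_empty_track(self):
        _, _, cal, milestones = _demo_setup()
        track = track_stream([], cal, milestones)
        assert track.empty and track.n_segments == 0

    def test_error_non_decreasing_with_pixel_noise(self):
        levels = [0.0, 1.0, 3.0, 8.0]
        rms = []
        for noise in levels:
            vals = []
            for seed in (0, 1, 2):
                dets, truth, cal, milestones = _demo_setup(noise_px=noise, seed=seed)
                track = track_stream(dets, cal, milestones, max_speed_mm_s=15.0)
                vals.append(track_error_stats(track, truth)["rms_3d_mm"])
            rms.append(np.mean(vals))
        for lo, hi in zip(rms, rms[1:]):
            assert hi >= 0.9 * lo
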