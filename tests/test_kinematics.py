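"""Body frame, wing Euler angles, blade elements and wingbeat summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from morphoflight import kinematics, simulate
from morphoflight.kinematics import (
    WING_NAMES,
    BodyPose,
    WingModel,
    WingPoseSeries,
    blade_element_states,
    body_frame,
    compose_wing_rotation,
    decompose_body_frame,
    stroke_plane,
    summarize_wingbeat,
    wing_euler_angles,
)
from morphoflight.trajectory import WingbeatSegment

X, Y, Z = np.eye(3)


class TestBodyFrame:
    def test_zero_angles_identity(self):
        assert np.allclose(body_frame(0, 0, 0), np.eye(3))

    def test_pitch_90_maps_body_axis_up(self):
        with pytest.warns(UserWarning, match="gimbal"):
            R = body_frame(0, 90, 0)
        assert np.allclose(R @ X, Z, atol=1e-12)

    @given(
        yaw=st.floats(-179, 179),
        pitch=st.floats(-85, 85),
        roll=st.floats(-179, 179),
    )
    def test_compose_decompose_round_trip(self, yaw, pitch, roll):
        R = body_frame(yaw, pitch, roll)
        y2, p2, r2 = decompose_body_frame(R)
        R2 = body_frame(y2, p2, r2)
        assert np.abs(R - R2).max() < 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            body_frame(np.nan, 0, 0)


class TestStrokePlane:
    def test_level_body_normal_is_world_x(self):
        point, normal = stroke_plane(body_frame(0, 0, 0), np.zeros(3), [0, 0.01, 0])
        assert np.allclose(normal, X)

    def test_vertical_body_normal_is_world_z(self):
        with pytest.warns(UserWarning):
            R = body_frame(0, 90, 0)
        _, normal = stroke_plane(R, np.zeros(3), np.zeros(3))
        assert np.allclose(normal, Z, atol=1e-12)

    def test_plane_contains_hinge(self):
        hinge = np.array([0.01, 0.006, 0.002])
        pos = np.array([0.3, -0.1, 0.5])
        R = body_frame(20, 35, 5)
        point, normal = stroke_plane(R, pos, hinge)
        assert np.allclose(point, pos + R @ hinge)
        assert np.dot(point - (pos + R @ hinge), normal) == pytest.approx(0.0)


class TestWingEulerAngles:
    def test_reference_pose_is_zero(self):
        for side in ("left", "right"):
            ang = wing_euler_angles(np.eye(3), side=side)
            assert ang.phi == pytest.approx(0.0, abs=1e-12)
            assert ang.theta == pytest.approx(0.0, abs=1e-12)
            assert ang.rotation == pytest.approx(0.0, abs=1e-12)

    def test_pure_deviation(self):
        R = compose_wing_rotation(0.0, 30.0, 0.0, side="left")
        ang = wing_euler_angles(R, side="left")
        assert ang.theta == pytest.approx(30.0, abs=1e-9)
        assert ang.rotation == pytest.approx(0.0, abs=1e-9)

    @given(
        phi=st.floats(-120, 120),
        theta=st.floats(-80, 80),
        H=st.floats(-89, 89),
        side=st.sampled_from(["left", "right"]),
    )
    def test_compose_decompose_round_trip(self, phi, theta, H, side):
        R = compose_wing_rotation(phi, theta, H, side=side)
        ang = wing_euler_angles(R, side=side)
        assert ang.phi == pytest.approx(phi, abs=1e-9)
        assert ang.theta == pytest.approx(theta, abs=1e-9)
        assert ang.rotation == pytest.approx(H, abs=1e-9)

    def test_degenerate_theta_flagged(self):
        R = compose_wing_rotation(10.0, 90.0, 0.0, side="left")
        ang = wing_euler_angles(R, side="left")
        assert ang.degenerate
        assert np.isnan(ang.phi)

    def test_left_right_mirror_same_angles(self):
        """A bilaterally symmetric stroke reads out identical angles per side."""
        RL = compose_wing_rotation(40.0, -15.0, 25.0, side="left")
        RR = compose_wing_rotation(40.0, -15.0, 25.0, side="right")
        # world-frame span axes mirror through the body x-z plane
        span_l = RL @ np.array([0.0, 1.0, 0.0])
        span_r = RR @ np.array([0.0, -1.0, 0.0])
        assert np.allclose(span_l * [1, -1, 1], span_r)


class TestWingModel:
    def test_requires_41_points(self):
        with pytest.raises(ValueError, match="41"):
            WingModel(outline=np.zeros((10, 2)))

    def test_elliptical_area(self):
        w = WingModel.elliptical(span=0.06, chord=0.04)
        # a 41-gon inscribed in the ellipse carries ~0.4% less area
        assert w.area == pytest.approx(np.pi * 0.06 * 0.04 / 4.0, rel=5e-3)
        assert w.span == pytest.approx(0.06)

    def test_element_centroids_cover_span(self):
        w = WingModel.elliptical(span=0.06, chord=0.04)
        c = w.element_centroids()
        assert len(c) == 10
        assert np.all(np.diff(c[:, 0]) > 0)
        assert c[0, 0] > 0 and c[-1, 0] < 0.06

    def test_file_round_trip(self, tmp_path):
        w = WingModel.elliptical(span=0.065, chord=0.045)
        path = tmp_path / "wing.txt"
        w.to_file(path)
        w2 = WingModel.from_file(path)
        assert np.allclose(w.outline, w2.outline)


def _still_body(n, fr=240.0, pitch=0.0):
    return BodyPose(
        position=np.zeros((n, 3)), yaw=np.zeros(n), pitch=np.full(n, pitch),
        roll=np.zeros(n), frame_rate=fr,
    )


class TestBladeElements:
    def test_pure_rotation_speed_linear_in_span(self):
        """Flapping about the hinge with a still body gives element speed
        proportional to spanwise position (omega * r)."""
        fr = 240.0
        n = 49
        t = np.arange(n) / fr
        phi = 30.0 * np.sin(2 * np.pi * 5.0 * t)
        wing = WingModel.elliptical(span=0.06, chord=0.04)
        pose = WingPoseSeries("fore_left", phi, np.zeros(n), np.zeros(n), fr)
        blades = blade_element_states(wing, pose, _still_body(n), np.zeros(3))
        r = wing.element_centroids()[:, 0]
        mid = 24  # away from the one-sided ends
        speeds = blades.speed[mid]
        fit = np.polyfit(r, speeds, 1)
        pred = np.polyval(fit, r)
        ss_res = np.sum((speeds - pred) ** 2)
        ss_tot = np.sum((speeds - speeds.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.999
        # chord in the stroke plane, motion in the stroke plane: alpha = 0
        assert np.nanmax(blades.alpha[mid]) < 1.0

    def test_velocity_in_wing_plane_zero_alpha(self):
        fr = 240.0
        n = 10
        body = BodyPose(
            position=np.arange(n)[:, None] * np.array([0.0, 1.0, 0.0]) / fr,
            yaw=np.zeros(n), pitch=np.zeros(n), roll=np.zeros(n), frame_rate=fr,
        )
        wing = WingModel.elliptical(span=0.06, chord=0.04)
        pose = WingPoseSeries("fore_left", np.zeros(n), np.zeros(n), np.zeros(n), fr)
        blades = blade_element_states(wing, pose, body, np.zeros(3))
        assert np.nanmax(blades.alpha) < 1e-6

    def test_velocity_along_normal_alpha_90(self):
        fr = 240.0
        n = 10
        # wing at reference: span +y, chord -z, normal = span x chord = -x
        body = BodyPose(
            position=np.arange(n)[:, None] * np.array([1.0, 0.0, 0.0]) / fr,
            yaw=np.zeros(n), pitch=np.zeros(n), roll=np.zeros(n), frame_rate=fr,
        )
        wing = WingModel.elliptical(span=0.06, chord=0.04)
        pose = WingPoseSeries("fore_left", np.zeros(n), np.zeros(n), np.zeros(n), fr)
        blades = blade_element_states(wing, pose, body, np.zeros(3))
        assert np.nanmin(blades.alpha) > 90.0 - 1e-6

    def test_alpha_invariant_to_speed_scaling(self):
        fr = 240.0
        n = 10
        wing = WingModel.elliptical(span=0.06, chord=0.04)
        pose = WingPoseSeries("fore_left", np.zeros(n), np.zeros(n), np.zeros(n), fr)
        alphas = []
        for scale in (0.5, 5.0):
            body = BodyPose(
                position=np.arange(n)[:, None] * np.array([scale, 0.0, scale]) / fr,
                yaw=np.zeros(n), pitch=np.zeros(n), roll=np.zeros(n), frame_rate=fr,
            )
            blades = blade_element_states(wing, pose, body, np.zeros(3))
            alphas.append(blades.alpha[5])
        assert np.allclose(alphas[0], alphas[1], atol=1e-9)

    def test_bilateral_symmetry_mirrors(self, default_flight):
        """Symmetric strokes give mirrored poses and identical alpha and speed."""
        cfg = default_flight.config
        bl = kinematics.blade_element_states(
            cfg.fore_wing, default_flight.wing_poses["fore_left"],
            default_flight.body_pose, cfg.hinges["fore_left"],
        )
        br = kinematics.blade_element_states(
            cfg.fore_wing, default_flight.wing_poses["fore_right"],
            default_flight.body_pose, cfg.hinges["fore_right"],
        )
        assert np.allclose(bl.speed, br.speed, atol=1e-9)
        assert np.allclose(bl.alpha, br.alpha, atol=1e-9, equal_nan=True)
        # y positions mirror through the body plane (yaw=roll=0 here)
        assert np.allclose(bl.positions[..., 1], -br.positions[..., 1], atol=1e-9)


class TestSummarizeWingbeat:
    def test_constant_pitch_passthrough(self, default_flight):
        n = default_flight.n_frames
        body = _still_body(n, pitch=67.0)
        blades = {
            w: blade_element_states(
                default_flight.config.wing_model(w), default_flight.wing_poses[w],
                body, default_flight.config.hinges[w],
            )
            for w in WING_NAMES
        }
        s = summarize_wingbeat(blades, default_flight.wing_poses, body,
                               default_flight.segments[0])
        assert s.beta_wingbeat == pytest.approx(67.0)

    def test_sinusoidal_stroke_amplitude_recovered(self):
        """A +/-57 deg sinusoidal stroke reads out a 114 deg amplitude."""
        fr, f = 240.0, 5.0
        n = 49
        t = np.arange(n) / fr
        phi = 57.0 * np.cos(2 * np.pi * f * t)
        pose = WingPoseSeries("fore_left", phi, np.zeros(n), np.zeros(n), fr)
        assert pose.amplitude(0, 48) == pytest.approx(114.0, abs=1e-9)

    def test_alpha_matches_truth_at_mid_stroke(self, default_flight):
        """Summaries built from truth poses agree with an independent
        mid-stroke evaluation of the blade-element alpha."""
        cfg = default_flight.config
        seg = default_flight.segments[1]
        blades = {
            w: blade_element_states(cfg.wing_model(w), default_flight.wing_poses[w],
                                    default_flight.body_pose, cfg.hinges[w])
            for w in WING_NAMES
        }
        s = summarize_wingbeat(blades, default_flight.wing_poses,
                               default_flight.body_pose, seg)
        mid_ds = (seg.start + seg.boundary) // 2
        mid_us = (seg.boundary + seg.end) // 2
        expected = np.mean(
            [
                np.nanmean(blades[w].alpha[m])
                for w in ("fore_left", "fore_right")
                for m in (mid_ds, mid_us)
            ]
        )
        assert s.alpha_fore == pytest.approx(expected, abs=1e-6)
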