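"""The synthetic-flight and cohort generators: the package's ground truth."""

import warnings

import numpy as np
import pandas as pd
import pytest

from morphoflight import geometry, simulate
from morphoflight.simulate import (
    CohortDesign,
    FlightSimConfig,
    generate_calibration_set,
    generate_cohort,
    project_flight,
    simulate_flight,
)


class TestSimulateFlight:
    def test_constant_45deg_climb_velocity_components(self):
        cfg = FlightSimConfig(climb_angle_profile=45.0, initial_speed=1.0)
        fl = simulate_flight(cfg)
        v = fl.trajectory.velocity
        assert np.allclose(v[:, 0], np.sqrt(2.0) / 2.0, atol=1e-12)
        assert np.allclose(v[:, 2], np.sqrt(2.0) / 2.0, atol=1e-12)

    def test_deterministic_from_config(self):
        a = simulate_flight(FlightSimConfig(seed=7))
        b = simulate_flight(FlightSimConfig(seed=7))
        assert np.array_equal(a.trajectory.position, b.trajectory.position)
        assert np.array_equal(a.wing_poses["fore_left"].phi, b.wing_poses["fore_left"].phi)
        assert a.reversal_events == b.reversal_events

    def test_reversal_spacing_from_frequency(self):
        fl = simulate_flight(FlightSimConfig(wingbeat_frequency=5.0, frame_rate=240.0))
        tops = [f for f, k in fl.reversal_events if k == "top"]
        assert np.all(np.diff(tops) == 240.0 / 5.0)

    def test_reversals_strictly_increasing(self, default_flight):
        frames = [f for f, _ in default_flight.reversal_events]
        assert np.all(np.diff(frames) > 0)

    def test_truth_metrics_consistent_with_trajectory(self, default_flight):
        """Stored truth metrics reproduce to <= 1e-9 relative error when
        recomputed from the truth trajectory."""
        from morphoflight.trajectory import wingbeat_metrics

        for seg, stored in zip(default_flight.segments, default_flight.truth_records):
            rec = wingbeat_metrics(default_flight.trajectory, seg)
            for k, v in rec.metrics().items():
                ref = getattr(stored, k)
                assert abs(v - ref) <= 1e-9 * max(abs(ref), 1.0)

    def test_non_finite_config_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            FlightSimConfig(initial_speed=np.nan)

    def test_invalid_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            FlightSimConfig(stroke_amplitude=200.0)


class TestProjectFlight:
    def test_noiseless_round_trip(self, default_flight, rig):
        views = project_flight(default_flight, rig, pixel_noise_sd=0.0)
        lm = default_flight.landmarks()
        uv, ok = geometry.project(rig[0], lm["body_centroid"])
        i = views.landmark_names.index("body_centroid")
        assert np.allclose(views.pixels[0, :, i, :][ok], uv[ok], atol=1e-12)

    def test_noise_sd_as_injected(self, default_flight, rig):
        views0 = project_flight(default_flight, rig, pixel_noise_sd=0.0)
        views = project_flight(default_flight, rig, pixel_noise_sd=0.5, seed=3)
        resid = (views.pixels - views0.pixels)[views.visible]
        assert resid.size >= 1e4
        assert np.std(resid) == pytest.approx(0.5, rel=0.1)

    def test_point_behind_camera_marked_missing(self, default_flight):
        # camera placed ahead of the flight, looking away from it
        cam_behind = geometry.CameraModel.look_at((-0.5, 0.0, 0.0), (-1.5, 0.0, 0.0))
        side = geometry.CameraModel.look_at((0.15, -1.0, 0.1), (0.15, 0.0, 0.1))
        views = project_flight(default_flight, [cam_behind, side])
        i = views.landmark_names.index("body_centroid")
        assert not views.visible[0, :, i].any()
        assert np.all(np.isnan(views.pixels[0, :, i]))
        assert views.visible[1, :, i].all()

    def test_too_few_cameras_rejected(self, default_flight, rig):
        with pytest.raises(ValueError, match="two cameras"):
            project_flight(default_flight, rig[:1])


class TestCalibrationSet:
    def test_noiseless_set_recovers_cameras(self, rig):
        cal = generate_calibration_set(rig, seed=1)
        for ci, cam in enumerate(rig):
            est, rmse = geometry.estimate_dlt(cal.points3d, cal.pixels[ci])
            assert rmse < 1e-6
            assert np.abs(est.L - cam.L).max() < 1e-6

    def test_wand_pairs_have_configured_separation(self, rig):
        cal = generate_calibration_set(rig, seed=2, wand_length=0.5)
        d = np.linalg.norm(
            cal.points3d[cal.wand_pairs[:, 0]] - cal.points3d[cal.wand_pairs[:, 1]],
            axis=1,
        )
        assert np.allclose(d, 0.5, atol=1e-12)

    def test_coplanar_volume_warns(self, rig):
        flat = ((-0.2, -0.2, 0.1), (0.4, 0.2, 0.1))
        with pytest.warns(UserWarning, match="coplanar"):
            generate_calibration_set(rig, volume=flat, seed=0, n_wand_pairs=0)

    def test_too_few_points_rejected(self, rig):
        with pytest.raises(ValueError, match="at least 6"):
            generate_calibration_set(rig, n_points=5)


class TestGenerateCohort:
    def test_zero_variance_collapses_to_group_means(self):
        design = CohortDesign(seed=0)
        for g in design.group_params:
            design.group_params[g] = {
                m: (mean, 0.0) for m, (mean, sd) in design.group_params[g].items()
            }
        cohort = generate_cohort(design)
        for g, params in design.group_params.items():
            sel = cohort.wingbeats[cohort.wingbeats.microhabitat == g]
            for m in ("u_hor", "u_ver", "f_wingbeat"):
                assert np.allclose(sel[m], params[m][0], atol=1e-12)

    def test_sample_mean_converges_to_configured_mean(self):
        """CLT bound: the canopy climb-angle mean lands within 3 sd/sqrt(n)."""
        mean, sd = 46.7, 17.0
        design = CohortDesign(
            group_species={"canopy": ["cisseis", "theseus"]},
            group_params={"canopy": {"gamma_climb": (mean, sd)}},
            counts={"canopy": {"individuals_per_species": 10,
                               "flights_per_individual": 50,
                               "wingbeats_per_flight": 10}},
            # iid wingbeats: the plain CLT bound applies to the sample mean
            variance_partition={"species": 0.0, "individual": 0.0, "flight": 0.0,
                                "wingbeat": 1.0},
            seed=5,
        )
        cohort = generate_cohort(design)
        n = len(cohort.wingbeats)
        assert n == 10000
        assert abs(cohort.wingbeats.gamma_climb.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_deterministic_from_seed(self):
        a = generate_cohort(CohortDesign(seed=9)).wingbeats
        b = generate_cohort(CohortDesign(seed=9)).wingbeats
        pd.testing.assert_frame_equal(a, b)

    def test_unmatched_tree_tips_rejected(self):
        design = CohortDesign(
            group_species={"canopy": ["not_a_species"]},
            group_params={"canopy": {"u_hor": (1.0, 0.1)}},
            counts={"canopy": {"individuals_per_species": 1,
                               "flights_per_individual": 1,
                               "wingbeats_per_flight": 1}},
        )
        with pytest.raises(ValueError, match="missing"):
            generate_cohort(design)

    def test_variance_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortDesign(variance_partition={"species": 0.5, "wingbeat": 0.4})

    def test_derived_metrics_are_consistent(self):
        wb = generate_cohort(CohortDesign(seed=1)).wingbeats
        assert np.allclose(wb.u_total, np.hypot(wb.u_hor, wb.u_ver), rtol=1e-12)
        assert np.allclose(
            wb.gamma_climb, np.degrees(np.arctan2(wb.u_ver, wb.u_hor)), rtol=1e-12
        )
        assert np.allclose(wb.dx_total, wb.u_total / wb.f_wingbeat, rtol=1e-12)

    def test_default_design_reproduces_group_summaries(self):
        """With the default (study-condition) design, the emergent group
        means of the derived metrics land near the configured summaries."""
        design = CohortDesign(seed=2)
        design.counts = {
            g: {"individuals_per_species": 20, "flights_per_individual": 10,
                "wingbeats_per_flight": 5}
            for g in design.counts
        }
        # suppress species-level drift for this mean check
        design.variance_partition = {"species": 0.0, "individual": 0.2,
                                     "flight": 0.2, "wingbeat": 0.6}
        wb = generate_cohort(design).wingbeats
        means = wb.groupby("microhabitat")[["gamma_climb", "u_total", "u_ver"]].mean()
        assert means.loc["canopy", "gamma_climb"] == pytest.approx(46.7, abs=2.5)
        assert means.loc["understory", "gamma_climb"] == pytest.approx(36.5, abs=2.5)
        assert means.loc["canopy", "u_total"] == pytest.approx(1.56, abs=0.1)
        assert means.loc["understory", "u_total"] == pytest.approx(1.32, abs=0.1)


class TestRegressionSample:
    def test_population_r2_matches_at_large_n(self):
        x, y = simulate.generate_regression_sample(
            n=20000, slope=0.8, intercept=0.0, x_mean=0.0, x_sd=1.0,
            r_squared=0.72, seed=0,
        )
        r = np.corrcoef(x, y)[0, 1]
        assert r**2 == pytest.approx(0.72, abs=0.02)

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_regression_sample(10, 1.0, 0.0, 0.0, 1.0, 1.5, 0)
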