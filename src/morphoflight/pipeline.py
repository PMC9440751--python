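"""End-to-end composition: from camera views to the statistics report.

``run_pipeline`` drives the whole chain.  In synthetic mode (no external
input files in the config) it simulates a climbing flight, films it through
a three-camera rig with pixel noise, calibrates the rig from a synthetic
wand set, reconstructs and smooths the body track, computes per-wingbeat
climb metrics and wingbeat kinematics, generates a hierarchical cohort and
runs the statistical battery; everything is deterministic given the config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from . import aero, geometry, io, kinematics, simulate, stats, trajectory
from .io import ProjectConfig

__all__ = ["run_pipeline", "PipelineResult", "reconstruct_landmarks",
           "recover_wing_poses", "ProjectConfig"]

log = logging.getLogger("morphoflight")

OUTLINE_INDICES = (4, 12, 20, 28, 36)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineResult:
    flight: simulate.SyntheticFlight | None
    cameras: list
    calibration_rmse: list[float]
    wand_result: geometry.WandCheckResult | None
    trajectory: trajectory.SmoothedTrajectory
    records: list[trajectory.WingbeatRecord]
    summaries: list[kinematics.WingbeatKinematicsSummary]
    cohort: simulate.CohortDataset | None
    stats_report: dict
    outdir: Path | None


def reconstruct_landmarks(
    views: simulate.DigitizedViews, cameras: list
) -> dict[str, geometry.Reconstruction3D]:
    """Triangulate every landmark track of a multi-camera view set."""
    out = {}
    for name in views.landmark_names:
        out[name] = geometry.triangulate_track(cameras, views.landmark_pixels(name))
    return out


def _smooth_series(x: np.ndarray, window: int) -> np.ndarray:
    if window < 5 or len(x) < window:
        return x
    if window % 2 == 0:
        window += 1
    return savgol_filter(x, window_length=window, polyorder=3)


def recover_wing_poses(
    landmarks3d: dict[str, geometry.Reconstruction3D],
    body_pose: kinematics.BodyPose,
    flight_config: simulate.FlightSimConfig,
    smooth_window: int = 11,
) -> dict[str, kinematics.WingPoseSeries]:
    """Fit per-frame wing orientations from reconstructed wing landmarks.

    Each wing's reconstructed tip and outline points are Kabsch-fitted
    against the rigid wing model, giving the world-frame wing basis, which
    is re-expressed in the body frame and decomposed into stroke-plane
    Euler angles.  The angle series are low-pass filtered (Savitzky-Golay)
    to suppress frame-to-frame digitization noise before any velocity
    differencing downstream.
    """
    n = body_pose.n_frames
    R_body = body_pose.rotations()
    poses = {}
    for wing in kinematics.WING_NAMES:
        side = "left" if wing.endswith("left") else "right"
        model = flight_config.wing_model(wing)
        local = np.vstack([model.tip, model.outline[list(OUTLINE_INDICES)]])
        names = [f"{wing}_tip"] + [f"{wing}_o{i}" for i in OUTLINE_INDICES]
        world = np.stack([landmarks3d[nm].points3d for nm in names], axis=1)  # (n, k, 3)
        hinge = landmarks3d[f"hinge_{wing}"].points3d
        phi = np.zeros(n)
        theta = np.zeros(n)
        rota = np.zeros(n)
        for t in range(n):
            A = kinematics.fit_rigid_orientation(local, world[t], hinge[t])
            span_w, chord_w = A[:, 0], A[:, 1]
            span_b = R_body[t].T @ span_w
            chord_b = R_body[t].T @ chord_w
            if side == "left":
                col_y, col_z = span_b, -chord_b
            else:
                col_y, col_z = -span_b, -chord_b
            R_wb = np.column_stack([np.cross(col_y, col_z), col_y, col_z])
            ang = kinematics.wing_euler_angles(R_wb, side=side)
            phi[t], theta[t], rota[t] = ang.phi, ang.theta, ang.rotation
        phi = _smooth_series(np.unwrap(phi, period=360.0), smooth_window)
        theta = _smooth_series(theta, smooth_window)
        rota = _smooth_series(rota, smooth_window)
        poses[wing] = kinematics.WingPoseSeries(
            wing=wing, phi=phi, theta=theta, rotation=rota,
            frame_rate=body_pose.frame_rate,
        )
    return poses


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: ProjectConfig) -> PipelineResult:
    """Run the full analysis chain described by ``config``.

    Returns the result bundle and, if ``config.outdir`` is set, persists
    every stage's outputs as CSV plus a plain-text statistics report.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline seed=%d outdir=%s", config.seed, outdir)

    # --- inputs: synthetic flight + rig, or external files -----------------
    flight = None
    if config.digitized_points is None:
        flight_cfg = simulate.FlightSimConfig(
            frame_rate=config.frame_rate,
            n_wingbeats=config.n_wingbeats,
            wingbeat_frequency=config.wingbeat_frequency,
            stroke_amplitude=config.stroke_amplitude,
            body_pitch=config.body_pitch,
            climb_angle_profile=config.climb_angle,
            initial_speed=config.flight_speed,
            pixel_noise_sd=config.pixel_noise_sd,
            seed=config.seed,
        )
        flight = simulate.simulate_flight(flight_cfg)
        true_cams = simulate.make_camera_rig()
        calset = simulate.generate_calibration_set(
            true_cams, pixel_noise_sd=config.pixel_noise_sd, seed=rng
        )
        cams = []
        cal_rmse = []
        for ci in range(len(true_cams)):
            cam, rmse = geometry.estimate_dlt(calset.points3d, calset.pixels[ci])
            cams.append(cam)
            cal_rmse.append(rmse)
        wand_pix = np.stack(
            [
                np.stack([calset.pixels[:, i, :], calset.pixels[:, j, :]])
                for i, j in calset.wand_pairs
            ]
        )
        wand = geometry.wand_check(cams, wand_pix, calset.wand_length)
        views = simulate.project_flight(flight, true_cams,
                                        pixel_noise_sd=config.pixel_noise_sd, seed=rng)
        reversal_events = flight.reversal_events
        if outdir is not None:
            io.write_digitized_views(views, outdir / "digitized_points.csv")
            io.write_dlt_csv(cams, outdir / "dlt_coefficients.csv")
            io.write_calibration_csv(calset, outdir / "calibration_points.csv")
            io.write_reversals(reversal_events, outdir / "reversals.csv")
        tracks = {c: views.to_dataframe(c) for c in range(views.n_cameras)}
        pixel_arrays = {
            name: views.landmark_pixels(name) for name in views.landmark_names
        }
        landmark_names = views.landmark_names
        frame_rate = config.frame_rate
        flight_config = flight_cfg
    else:
        tracks = io.read_digitized_points(config.digitized_points)
        cams = io.read_dlt_csv(config.dlt_coefficients)
        cal_rmse, wand = [], None
        reversal_events = io.read_reversals(config.reversals) if config.reversals else None
        landmark_names = sorted(
            set().union(*[set(t["point_id"]) for t in tracks.values()])
        )
        n_frames = 1 + max(int(t["frame"].max()) for t in tracks.values())
        pixel_arrays = {
            name: io.tracks_to_pixel_array(tracks, name, n_frames)
            for name in landmark_names
        }
        frame_rate = config.frame_rate
        flight_config = simulate.FlightSimConfig(frame_rate=frame_rate)

    # --- reconstruction and smoothing --------------------------------------
    recon = {
        name: geometry.triangulate_track(cams, arr)
        for name, arr in pixel_arrays.items()
    }
    if "body_centroid" not in recon:
        raise PipelineError("stage 'reconstruct' failed: no 'body_centroid' track "
                            "in the digitized points")
    traj = trajectory.kalman_smooth(
        recon["body_centroid"].points3d,
        frame_rate,
        process_noise=config.kalman_process_noise,
        obs_noise=config.kalman_obs_noise,
    )
    if outdir is not None:
        io.write_trajectory(traj, outdir / "trajectory.csv")

    # --- wingbeat metrics ---------------------------------------------------
    records = []
    segments = []
    if reversal_events is not None:
        segments = trajectory.segment_wingbeats(reversal_events, frame_rate)
        records = [
            trajectory.wingbeat_metrics(traj, seg, labels={"wingbeat_index": i})
            for i, seg in enumerate(segments)
        ]
        if outdir is not None:
            io.write_wingbeat_table(records, outdir / "wingbeats.csv")

    # --- wing kinematics ----------------------------------------------------
    summaries = []
    wing_landmarks_present = all(
        f"hinge_{w}" in pixel_arrays and f"{w}_tip" in pixel_arrays
        for w in kinematics.WING_NAMES
    ) and {"head", "tail"} <= set(landmark_names)
    if wing_landmarks_present and segments:
        # average the fore and hind hinge pairs: the short hinge baseline makes
        # roll the noisiest body angle, and the roll jitter propagates into
        # blade-element velocities
        hinge_left = 0.5 * (recon["hinge_fore_left"].points3d
                            + recon["hinge_hind_left"].points3d)
        hinge_right = 0.5 * (recon["hinge_fore_right"].points3d
                             + recon["hinge_hind_right"].points3d)
        body_pose = kinematics.body_pose_from_landmarks(
            head=recon["head"].points3d,
            tail=recon["tail"].points3d,
            hinge_left=hinge_left,
            hinge_right=hinge_right,
            centroid=traj.position,
            frame_rate=frame_rate,
        )
        body_pose = kinematics.BodyPose(
            position=body_pose.position,
            yaw=_smooth_series(np.unwrap(body_pose.yaw, period=360.0),
                               config.angle_smooth_window),
            pitch=np.clip(_smooth_series(body_pose.pitch, config.angle_smooth_window),
                          -90.0, 90.0),
            roll=_smooth_series(np.unwrap(body_pose.roll, period=360.0),
                                config.angle_smooth_window),
            frame_rate=frame_rate,
        )
        wing_poses = recover_wing_poses(
            recon, body_pose, flight_config, smooth_window=config.angle_smooth_window
        )
        blades = {
            w: kinematics.blade_element_states(
                flight_config.wing_model(w), wing_poses[w], body_pose,
                flight_config.hinges[w],
            )
            for w in kinematics.WING_NAMES
        }
        summaries = [
            kinematics.summarize_wingbeat(blades, wing_poses, body_pose, seg)
            for seg in segments
        ]
        if outdir is not None:
            rows = []
            for w, p in wing_poses.items():
                for t in range(p.n_frames):
                    rows.append({"frame": t, "wing": w, "phi_deg": p.phi[t],
                                 "theta_deg": p.theta[t], "rotation_deg": p.rotation[t]})
            pd.DataFrame(rows).to_csv(outdir / "wing_angles.csv", index=False)
            pd.DataFrame([vars(s) for s in summaries]).to_csv(
                outdir / "wingbeat_kinematics.csv", index=False
            )

    # --- cohort + statistics ------------------------------------------------
    design = simulate.CohortDesign(seed=int(rng.integers(2**31 - 1)))
    cohort = simulate.generate_cohort(design)
    report = cohort_statistics(cohort, n_sim=config.n_sim,
                               anova_order=list(config.anova_order),
                               seed=config.seed)
    if outdir is not None:
        io.write_wingbeat_table(cohort.wingbeats, outdir / "cohort_wingbeats.csv")
        io.write_morphology(cohort.morphology, outdir / "cohort_morphology.csv")
        (outdir / "cohort_tree.nwk").write_text(cohort.tree + "\n")
        for metric, tab in report["anova"].items():
            tab.table.to_csv(outdir / f"anova_{metric}.csv")
        (outdir / "report.txt").write_text(format_report(report))

    return PipelineResult(
        flight=flight,
        cameras=cams,
        calibration_rmse=cal_rmse,
        wand_result=wand,
        trajectory=traj,
        records=records,
        summaries=summaries,
        cohort=cohort,
        stats_report=report,
        outdir=outdir,
    )


def cohort_statistics(
    cohort: simulate.CohortDataset,
    n_sim: int = 1000,
    anova_order=None,
    seed: int = 0,
) -> dict:
    """The statistical battery applied to a cohort dataset.

    Sequential ANOVA per wingbeat metric (habitat entered first), MANOVA
    across all eight metrics, phylogenetic ANOVA of the species means of
    climb angle and flight speed, a Wilcoxon rank-sum test of the
    weight-normalized wing area, and the percent group contrasts.
    """
    wb = cohort.wingbeats
    order = list(anova_order or ["microhabitat", "species", "individual",
                                 "flight", "wingbeat_index"])
    metrics = [m for m in trajectory.METRIC_NAMES if wb[m].notna().all()]
    report: dict = {"anova": {}, "n_wingbeats": len(wb)}
    for m in metrics:
        report["anova"][m] = stats.sequential_anova(wb, m, order)
    lam, F, p = stats.manova_wilks(wb, metrics, "microhabitat")
    report["manova"] = {"wilks_lambda": lam, "F": F, "p": p}

    sp = wb.groupby(["species", "microhabitat"], as_index=False)[metrics].mean()
    report["phylo_anova"] = {}
    for m in ("gamma_climb", "u_total"):
        if m in metrics:
            res = stats.phylogenetic_anova(
                sp[m].to_numpy(), sp["microhabitat"].to_numpy(), cohort.tree,
                species=list(sp["species"]), n_sim=max(n_sim, 100), seed=seed,
            )
            report["phylo_anova"][m] = res

    morph = cohort.morphology.copy()
    if {"mass_g", "wing_area_cm2"} <= set(morph.columns):
        morph["s_over_mg"] = [
            aero.weight_normalized_wing_area(a, m)[0]
            for a, m in zip(morph["wing_area_cm2"], morph["mass_g"])
        ]
        grp = morph.groupby("microhabitat")["s_over_mg"]
        groups = {g: v.to_numpy() for g, v in grp}
        if len(groups) == 2:
            (ga, va), (gb, vb) = sorted(groups.items())
            W, p_w = stats.wilcoxon_rank_sum(va, vb)
            report["wilcoxon_s_over_mg"] = {"W": W, "p": p_w,
                                            "groups": (ga, gb)}

    means = wb.groupby("microhabitat")[metrics].mean()
    if {"canopy", "understory"} <= set(means.index):
        report["contrasts_pct"] = {
            m: stats.percent_difference(means.loc["canopy", m],
                                        means.loc["understory", m], ndigits=1)
            for m in metrics
        }
    return report


def format_report(report: dict) -> str:
    lines = [f"Cohort statistics ({report['n_wingbeats']} wingbeats)", ""]
    for m, tab in report["anova"].items():
        micro = tab.table.loc["microhabitat"]
        lines.append(
            f"ANOVA {m}: microhabitat F({int(micro['df'])},"
            f"{int(tab.table.loc['residual', 'df'])}) = {micro['F']:.2f}, "
            f"p = {micro['p']:.3g}"
        )
    man = report["manova"]
    lines.append(
        f"MANOVA: Wilks' lambda = {man['wilks_lambda']:.3f}, "
        f"F = {man['F']:.2f}, p = {man['p']:.3g}"
    )
    for m, res in report.get("phylo_anova", {}).items():
        lines.append(
            f"Phylogenetic ANOVA {m}: F = {res.f_observed:.2f}, "
            f"p_phylo = {res.p_phylo:.3f} (standard p = {res.p_standard:.3f})"
        )
    if "wilcoxon_s_over_mg" in report:
        w = report["wilcoxon_s_over_mg"]
        lines.append(f"Wilcoxon S/mg {w['groups']}: W = {w['W']:.1f}, p = {w['p']:.3g}")
    if "contrasts_pct" in report:
        lines.append("")
        lines.append("Canopy vs understory contrasts (%):")
        for m, v in report["contrasts_pct"].items():
            lines.append(f"  {m}: {v:+.1f}%")
    return "\n".join(lines) + "\n"
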