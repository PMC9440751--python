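"""File formats: digitized pixel tracks, DLT coefficients, wingbeat tables,
morphology, ensemble traces, trees and the project configuration.

All tabular formats are header-carrying UTF-8 CSV with empty fields for
missing values; DLT coefficients use the de-facto 11-rows-by-one-column-
per-camera layout; trees are newick; configuration is YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import CalibrationPoints, CameraModel
from .simulate import DigitizedViews
from .trajectory import METRIC_NAMES, SmoothedTrajectory, WingbeatRecord

__all__ = [
    "read_digitized_points",
    "write_digitized_views",
    "tracks_to_pixel_array",
    "read_dlt_csv",
    "write_dlt_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_wingbeat_table",
    "write_wingbeat_table",
    "read_morphology",
    "write_morphology",
    "write_trajectory",
    "read_trajectory",
    "write_reversals",
    "read_reversals",
    "write_ensemble_trace",
    "ProjectConfig",
]

_DIGITIZED_COLUMNS = ["frame", "point_id", "camera", "u_px", "v_px", "visible"]


def read_digitized_points(path) -> dict[int, pd.DataFrame]:
    """Read a digitized pixel-track CSV into per-camera tables.

    The file must carry the columns frame, point_id, camera, u_px, v_px,
    visible.  Rows with visible=0 become NaN pixels (missing, never
    zero-filled).  Frames must be non-decreasing within each
    (camera, point_id) track; violations are reported with row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DIGITIZED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.copy()
    invisible = df["visible"].astype(int) == 0
    df.loc[invisible, ["u_px", "v_px"]] = np.nan
    df["u_px"] = pd.to_numeric(df["u_px"], errors="coerce")
    df["v_px"] = pd.to_numeric(df["v_px"], errors="coerce")
    bad_rows = []
    for (cam, pid), grp in df.groupby(["camera", "point_id"], sort=False):
        frames = grp["frame"].to_numpy()
        drops = np.flatnonzero(np.diff(frames) < 0)
        bad_rows.extend(grp.index[d + 1] for d in drops)
    if bad_rows:
        rows = sorted(int(r) + 2 for r in bad_rows)  # 1-based incl. header
        raise ValueError(f"{path}: non-monotone frame numbers at file rows {rows}")
    return {int(cam): grp.drop(columns="camera").reset_index(drop=True)
            for cam, grp in df.groupby("camera", sort=True)}


def write_digitized_views(views: DigitizedViews, path) -> None:
    """Write a :class:`DigitizedViews` as one tidy multi-camera CSV."""
    frames = []
    for cam in range(views.n_cameras):
        df = views.to_dataframe(cam)
        df.insert(2, "camera", cam)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tracks_to_pixel_array(
    tracks: dict[int, pd.DataFrame], point_id: str, n_frames: int | None = None
) -> np.ndarray:
    """Assemble one landmark's pixels as (n_cameras, n_frames, 2) with NaN gaps."""
    cams = sorted(tracks)
    if n_frames is None:
        n_frames = 1 + max(int(t["frame"].max()) for t in tracks.values())
    out = np.full((len(cams), n_frames, 2), np.nan)
    for i, cam in enumerate(cams):
        t = tracks[cam]
        sel = t[t["point_id"] == point_id]
        fr = sel["frame"].to_numpy(dtype=int)
        out[i, fr, 0] = sel["u_px"].to_numpy(dtype=float)
        out[i, fr, 1] = sel["v_px"].to_numpy(dtype=float)
    return out


# -- DLT coefficients -------------------------------------------------------


def write_dlt_csv(cameras: list[CameraModel], path) -> None:
    """11-row CSV, one column per camera (DLTdv / easyWand layout)."""
    M = np.column_stack([c.L for c in cameras])
    pd.DataFrame(M, columns=[f"camera_{i}" for i in range(len(cameras))]).to_csv(
        path, index=False
    )


def read_dlt_csv(path) -> list[CameraModel]:
    df = pd.read_csv(path)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != 11:
        raise ValueError(f"{path}: DLT file must have 11 coefficient rows, got {M.shape[0]}")
    return [CameraModel(L=M[:, i]) for i in range(M.shape[1])]


# -- Calibration points -----------------------------------------------------


def write_calibration_csv(cal: CalibrationPoints, path) -> None:
    """Long-format calibration CSV: one row per point per camera."""
    rows = []
    pair_of = {}
    end_of = {}
    if cal.wand_pairs is not None:
        for k, (i, j) in enumerate(np.asarray(cal.wand_pairs, dtype=int)):
            pair_of[i], end_of[i] = k, 0
            pair_of[j], end_of[j] = k, 1
    n_cams = cal.pixels.shape[0]
    for p, xyz in enumerate(cal.points3d):
        for cam in range(n_cams):
            u, v = cal.pixels[cam, p]
            rows.append(
                {
                    "point": p,
                    "x_m": xyz[0],
                    "y_m": xyz[1],
                    "z_m": xyz[2],
                    "camera": cam,
                    "u_px": u if np.isfinite(u) else "",
                    "v_px": v if np.isfinite(v) else "",
                    "wand_pair": pair_of.get(p, ""),
                    "wand_end": end_of.get(p, ""),
                }
            )
    df = pd.DataFrame(rows)
    df["wand_length_m"] = cal.wand_length if cal.wand_length is not None else ""
    df.to_csv(path, index=False)


def read_calibration_csv(path) -> CalibrationPoints:
    df = pd.read_csv(path)
    pts = (
        df.drop_duplicates("point").sort_values("point")[["x_m", "y_m", "z_m"]]
        .to_numpy(dtype=float)
    )
    cams = sorted(df["camera"].unique())
    n = len(pts)
    pixels = np.full((len(cams), n, 2), np.nan)
    for i, cam in enumerate(cams):
        sel = df[df["camera"] == cam].sort_values("point")
        idx = sel["point"].to_numpy(dtype=int)
        pixels[i, idx, 0] = pd.to_numeric(sel["u_px"], errors="coerce")
        pixels[i, idx, 1] = pd.to_numeric(sel["v_px"], errors="coerce")
    wand_pairs = None
    wand_length = None
    wp = df.drop_duplicates("point")
    wp = wp[pd.to_numeric(wp["wand_pair"], errors="coerce").notna()]
    if len(wp):
        pairs = {}
        for _, row in wp.iterrows():
            pairs.setdefault(int(row["wand_pair"]), {})[int(row["wand_end"])] = int(row["point"])
        wand_pairs = np.array([[p[0], p[1]] for _, p in sorted(pairs.items())])
        wl = pd.to_numeric(df["wand_length_m"], errors="coerce").dropna()
        wand_length = float(wl.iloc[0]) if len(wl) else None
    return CalibrationPoints(points3d=pts, pixels=pixels, wand_pairs=wand_pairs,
                             wand_length=wand_length)


# -- Wingbeat records and trajectories --------------------------------------

_LABELS = ["microhabitat", "species", "individual", "flight", "wingbeat_index"]


def write_wingbeat_table(records: list[WingbeatRecord] | pd.DataFrame, path) -> None:
    """Tidy per-wingbeat CSV (one labelled row per wingbeat)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([{**r.metrics(), **{k: getattr(r, k) for k in _LABELS}}
                           for r in records])
    df.to_csv(path, index=False)


def read_wingbeat_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing wingbeat metric columns {missing}")
    return df


def write_morphology(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_morphology(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("mass_g", "wing_area_cm2"):
        if c not in df.columns:
            raise ValueError(f"{path}: morphology file must carry column {c!r}")
    return df


def write_trajectory(traj: SmoothedTrajectory, path) -> None:
    cols = {"time_s": traj.time}
    for name, arr in (("pos", traj.position), ("vel", traj.velocity),
                      ("acc", traj.acceleration)):
        for i, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trajectory(path, frame_rate: float | None = None) -> SmoothedTrajectory:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if frame_rate is None:
        frame_rate = 1.0 / np.median(np.diff(t))
    get = lambda p: df[[f"{p}_x", f"{p}_y", f"{p}_z"]].to_numpy(dtype=float)
    return SmoothedTrajectory(time=t, position=get("pos"), velocity=get("vel"),
                              acceleration=get("acc"), frame_rate=float(frame_rate))


def write_reversals(events: list[tuple[int, str]], path) -> None:
    pd.DataFrame(events, columns=["frame", "event"]).to_csv(path, index=False)


def read_reversals(path) -> list[tuple[int, str]]:
    df = pd.read_csv(path)
    return [(int(f), str(e)) for f, e in zip(df["frame"], df["event"])]


def write_ensemble_trace(trace, path) -> None:
    pd.DataFrame(
        {
            "phase": trace.phase,
            "fraction": trace.fraction,
            "mean": trace.mean,
            "ci_low": trace.ci_low,
            "ci_high": trace.ci_high,
        }
    ).to_csv(path, index=False)


# -- Project configuration --------------------------------------------------


@dataclass
class ProjectConfig:
    """End-to-end pipeline configuration (YAML-serializable).

    Paths may be omitted for a purely synthetic run, in which case the
    pipeline generates its inputs from ``seed`` and the flight/cohort
    settings below.
    """

    seed: int = 0
    outdir: str = "morphoflight_out"
    frame_rate: float = 240.0
    # synthetic flight settings
    n_wingbeats: int = 3
    wingbeat_frequency: float = 5.0
    stroke_amplitude: float = 114.0
    body_pitch: float = 55.0
    climb_angle: float = 40.0
    flight_speed: float = 1.4
    pixel_noise_sd: float = 0.5
    # optional externally supplied inputs
    digitized_points: str | None = None
    dlt_coefficients: str | None = None
    reversals: str | None = None
    morphology: str | None = None
    tree: str | None = None
    # processing settings
    kalman_process_noise: float = 500.0
    kalman_obs_noise: float = 2e-3
    blade_elements: int = 10
    angle_smooth_window: int = 11
    # aerodynamic constants
    rho: float = 1.17
    g: float = 9.81
    c_t_alpha: float = 1.0
    # statistics settings
    n_sim: int = 1000
    anova_order: tuple = ("microhabitat", "species", "individual", "flight",
                          "wingbeat_index")

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.anova_order is not None:
            cfg.anova_order = tuple(cfg.anova_order)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["anova_order"] = list(data["anova_order"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate(self) -> None:
        if self.digitized_points is not None and self.dlt_coefficients is None:
            raise ValueError(
                "config field 'dlt_coefficients' is required when raw "
                "'digitized_points' are supplied"
            )
        if self.frame_rate <= 0 or self.blade_elements < 1:
            raise ValueError("frame_rate must be positive and blade_elements >= 1")
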