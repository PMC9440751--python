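"""Ground-truthed synthetic flights, camera views and hierarchical cohorts.

Every downstream stage of the package (calibration, triangulation,
smoothing, wingbeat metrics, blade-element kinematics, statistics) is
testable against the exact truth produced here, emulating the study system:
a climbing butterfly filmed at 240 frames/s by three orthogonally placed
cameras, and a two-microhabitat (canopy vs understory) cohort of species,
individuals, flights and wingbeats.

The default numerical conditions -- 240 Hz recording, ~5 Hz wingbeat,
stroke amplitudes above 110 deg, climb angles of 35-50 deg, speeds around
1.3-1.6 m/s, body pitch of 44-67 deg, weight-normalized wing areas near
2 m^2/N -- are the published group-level summaries for canopy and
understory *Morpho* butterflies, stored in :data:`CANOPY` and
:data:`UNDERSTORY`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from . import geometry, kinematics, trajectory
from .geometry import CalibrationPoints, CameraModel
from .kinematics import WING_NAMES, BodyPose, WingModel, WingPoseSeries
from .trajectory import SmoothedTrajectory, WingbeatRecord, WingbeatSegment

__all__ = [
    "GroupSummary",
    "CANOPY",
    "UNDERSTORY",
    "MORPHO_TREE",
    "FlightSimConfig",
    "SyntheticFlight",
    "DigitizedViews",
    "CohortDesign",
    "CohortDataset",
    "simulate_flight",
    "project_flight",
    "generate_calibration_set",
    "generate_cohort",
    "generate_regression_sample",
    "make_camera_rig",
]


# ---------------------------------------------------------------------------
# Study conditions: group-level summaries (mean, SD)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Group-level (mean, SD) summaries defining one microhabitat's flyers.

    Units: angles deg, speeds m/s, frequency Hz, wing area cm^2 (both wing
    pairs), mass g, S/mg m^2/N.  ``u_total_at_50deg`` is the mean flight
    speed of wingbeats at a matched 50 deg climb angle, used for the
    equal-climb-angle speed contrast.
    """

    microhabitat: str
    gamma_climb: tuple[float, float]
    u_total: tuple[float, float]
    u_ver: tuple[float, float]
    u_hor: tuple[float, float]
    f_wingbeat: tuple[float, float]
    beta_wingbeat: tuple[float, float]
    stroke_amplitude: tuple[float, float]
    hind_deviation: tuple[float, float]
    s_over_mg: tuple[float, float]
    wing_area_cm2: tuple[float, float]
    mass_g: tuple[float, float]
    u_total_at_50deg: tuple[float, float]


CANOPY = GroupSummary(
    microhabitat="canopy",
    gamma_climb=(46.7, 17.0),
    u_total=(1.56, 0.56),
    u_ver=(1.07, 0.46),
    u_hor=(1.00, 0.40),
    f_wingbeat=(4.0, 0.8),
    beta_wingbeat=(67.0, 9.0),
    stroke_amplitude=(114.0, 19.0),
    hind_deviation=(-56.0, 4.0),
    s_over_mg=(2.24, 0.51),
    wing_area_cm2=(100.42, 19.27),
    mass_g=(0.457, 0.10),
    u_total_at_50deg=(1.55, 0.51),
)

UNDERSTORY = GroupSummary(
    microhabitat="understory",
    gamma_climb=(36.5, 16.0),
    u_total=(1.32, 0.49),
    u_ver=(0.72, 0.35),
    u_hor=(0.98, 0.40),
    f_wingbeat=(4.6, 0.8),
    beta_wingbeat=(44.0, 10.0),
    stroke_amplitude=(128.0, 26.0),
    hind_deviation=(-48.0, 3.0),
    s_over_mg=(1.74, 0.88),
    wing_area_cm2=(79.28, 21.15),
    mass_g=(0.464, 0.10),
    u_total_at_50deg=(1.24, 0.40),
)

#: Seven-species ultrametric phylogeny (canopy clade: cisseis + theseus),
#: arbitrary but fixed branch lengths on a depth-3 tree.
MORPHO_TREE = (
    "((cisseis:1.0,theseus:1.0):2.0,"
    "((achilles:1.5,helenor:1.5):0.75,"
    "(menelaus:1.25,(deidamia:0.75,sulkowskyi:0.75):0.5):1.0):0.75);"
)

CANOPY_SPECIES = ("cisseis", "theseus")
UNDERSTORY_SPECIES = ("achilles", "helenor", "menelaus", "deidamia", "sulkowskyi")


# ---------------------------------------------------------------------------
# Flight simulation
# ---------------------------------------------------------------------------


def _profile(p):
    """Normalize a constant or callable profile to a vectorized callable of t."""
    if callable(p):
        return lambda t: np.asarray(p(t), dtype=float)
    value = float(p)
    return lambda t: np.full_like(np.asarray(t, dtype=float), value)


_DEFAULT_HINGES = {
    "fore_left": np.array([0.010, 0.006, 0.002]),
    "fore_right": np.array([0.010, -0.006, 0.002]),
    "hind_left": np.array([0.000, 0.005, 0.000]),
    "hind_right": np.array([0.000, -0.005, 0.000]),
}


@dataclass
class FlightSimConfig:
    """Configuration of one synthetic climbing flight.

    Wing-angle profiles default to minimal periodic kinematics: a cosine
    stroke of amplitude ``stroke_amplitude`` (peak-to-peak, so the wing is
    at the stroke top at frame 0), a double-frequency sinusoidal deviation
    about a backward-offset mean, and a rotation angle flipping sign
    between half-strokes.  Any profile can be overridden with a callable of
    time (seconds, degrees out).
    """

    frame_rate: float = 240.0  # Hz
    n_wingbeats: int = 3
    wingbeat_frequency: float = 5.0  # Hz
    stroke_amplitude: float = 114.0  # deg, peak-to-peak (fore wings)
    hind_amplitude_ratio: float = 0.85
    deviation_profile: object | None = None  # deg; default set in simulate_flight
    rotation_profile: object | None = None  # deg
    body_pitch: object = 55.0  # deg
    initial_speed: float = 1.4  # m/s
    climb_angle_profile: object = 40.0  # deg
    fore_wing: WingModel | None = None
    hind_wing: WingModel | None = None
    hinges: dict | None = None
    head_offset: float = 0.03  # m, centroid -> head along the body axis
    tail_offset: float = 0.03  # m, centroid -> tail
    pixel_noise_sd: float = 0.0  # px, used by project_flight defaults
    position_noise_sd: float = 0.0  # m, optional noise on exported raw tracks
    mass_g: float = 0.46
    seed: int = 0

    def __post_init__(self):
        for name in ("frame_rate", "wingbeat_frequency", "initial_speed",
                     "stroke_amplitude", "hind_amplitude_ratio"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.wingbeat_frequency <= 0:
            raise ValueError("wingbeat_frequency must be positive")
        if self.n_wingbeats < 1:
            raise ValueError("n_wingbeats must be at least 1")
        if not (0.0 <= self.stroke_amplitude <= 180.0):
            raise ValueError("stroke amplitude must lie in [0, 180] deg")
        if self.fore_wing is None:
            self.fore_wing = WingModel.elliptical(span=0.065, chord=0.045)
        if self.hind_wing is None:
            self.hind_wing = WingModel.elliptical(span=0.050, chord=0.050)
        if self.hinges is None:
            self.hinges = {k: v.copy() for k, v in _DEFAULT_HINGES.items()}

    def wing_model(self, wing: str) -> WingModel:
        return self.fore_wing if wing.startswith("fore") else self.hind_wing


@dataclass
class SyntheticFlight:
    """A simulated flight with full ground truth."""

    config: FlightSimConfig
    trajectory: SmoothedTrajectory  # truth body states
    body_pose: BodyPose
    wing_poses: dict[str, WingPoseSeries]
    reversal_events: list[tuple[int, str]]
    segments: list[WingbeatSegment]
    truth_records: list[WingbeatRecord]
    truth_summaries: list  # WingbeatKinematicsSummary per segment

    @property
    def n_frames(self) -> int:
        return self.trajectory.n_frames

    def landmarks(self, outline_indices=(4, 12, 20, 28, 36)) -> dict[str, np.ndarray]:
        """World positions of the digitizable landmarks, name -> (n, 3)."""
        cfg = self.config
        n = self.n_frames
        R_body = self.body_pose.rotations()
        pos = self.trajectory.position
        out = {
            "body_centroid": pos.copy(),
            "head": pos + R_body @ np.array([cfg.head_offset, 0.0, 0.0]),
            "tail": pos - R_body @ np.array([cfg.tail_offset, 0.0, 0.0]),
        }
        for wing in WING_NAMES:
            hinge = cfg.hinges[wing]
            out[f"hinge_{wing}"] = pos + R_body @ hinge
            model = cfg.wing_model(wing)
            side = "left" if wing.endswith("left") else "right"
            R_wing = self.wing_poses[wing].rotations()
            locals2d = np.vstack([model.tip, model.outline[list(outline_indices)]])
            names = [f"{wing}_tip"] + [f"{wing}_o{i}" for i in outline_indices]
            pts = np.zeros((len(names), n, 3))
            for t in range(n):
                span, chord, _ = kinematics._wing_basis_world(R_body[t], R_wing[t], side)
                origin = pos[t] + R_body[t] @ hinge
                pts[:, t] = origin + locals2d[:, [0]] * span + locals2d[:, [1]] * chord
            for name, p in zip(names, pts):
                out[name] = p
        return out


def simulate_flight(config: FlightSimConfig) -> SyntheticFlight:
    """Simulate an articulated climbing flyer (rigid body + 4 flat wings).

    The body follows the configured climb-angle and speed profile (velocity
    is evaluated analytically from the profiles and integrated on a fine
    sub-frame grid); the wings follow the configured periodic Euler-angle
    profiles in the stroke-plane convention.  All truth fields -- states,
    reversal frames, per-wingbeat climb metrics and wingbeat kinematics
    summaries -- are filled.  Output is fully determined by the config.
    """
    cfg = config
    f = cfg.wingbeat_frequency
    fr = cfg.frame_rate
    period = fr / f  # frames per wingbeat
    n_frames = int(round(cfg.n_wingbeats * period)) + 1
    t_frames = np.arange(n_frames) / fr

    gamma = _profile(cfg.climb_angle_profile)
    speed = _profile(cfg.initial_speed)
    pitch = _profile(cfg.body_pitch)

    def velocity_fn(t):
        t = np.asarray(t, dtype=float)
        g = np.radians(gamma(t))
        s = speed(t)
        return np.stack([s * np.cos(g), np.zeros_like(s), s * np.sin(g)], axis=-1)

    # position by cumulative trapezoid on a 16x sub-frame grid (exact for
    # constant profiles, ~1e-9 m accurate for smooth ones)
    sub = 16
    t_fine = np.arange((n_frames - 1) * sub + 1) / (fr * sub)
    v_fine = velocity_fn(t_fine)
    dtf = 1.0 / (fr * sub)
    pos_fine = np.vstack(
        [np.zeros(3), np.cumsum((v_fine[1:] + v_fine[:-1]) / 2.0 * dtf, axis=0)]
    )
    position = pos_fine[::sub]
    velocity = velocity_fn(t_frames)
    h = 1e-6
    acceleration = (velocity_fn(t_frames + h) - velocity_fn(t_frames - h)) / (2.0 * h)

    traj = SmoothedTrajectory(
        time=t_frames,
        position=position,
        velocity=velocity,
        acceleration=acceleration,
        frame_rate=fr,
    )

    body_pose = BodyPose(
        position=position,
        yaw=np.zeros(n_frames),
        pitch=pitch(t_frames),
        roll=np.zeros(n_frames),
        frame_rate=fr,
    )

    # wing angle profiles (identical left/right in the mirrored convention)
    two_pi_f = 2.0 * np.pi * f
    if cfg.deviation_profile is None:
        dev_fore = lambda t: -10.0 + 8.0 * np.sin(2.0 * two_pi_f * np.asarray(t))
        dev_hind = lambda t: -48.0 + 6.0 * np.sin(2.0 * two_pi_f * np.asarray(t))
    else:
        dev_fore = dev_hind = _profile(cfg.deviation_profile)
    if cfg.rotation_profile is None:
        rot = lambda t: 40.0 * np.sin(two_pi_f * np.asarray(t))
    else:
        rot = _profile(cfg.rotation_profile)

    wing_poses = {}
    for wing in WING_NAMES:
        amp = cfg.stroke_amplitude * (1.0 if wing.startswith("fore") else cfg.hind_amplitude_ratio)
        phi = (amp / 2.0) * np.cos(two_pi_f * t_frames)
        theta = (dev_fore if wing.startswith("fore") else dev_hind)(t_frames)
        rota = rot(t_frames)
        wing_poses[wing] = WingPoseSeries(
            wing=wing, phi=phi, theta=np.asarray(theta), rotation=np.asarray(rota),
            frame_rate=fr,
        )

    # stroke reversals: phi is extremal at integer half-periods
    events = []
    for k in range(2 * cfg.n_wingbeats + 1):
        frame = int(round(k * period / 2.0))
        events.append((min(frame, n_frames - 1), "top" if k % 2 == 0 else "bottom"))
    segments = trajectory.segment_wingbeats(events, fr)

    truth_records = [
        trajectory.wingbeat_metrics(traj, seg, labels={"wingbeat_index": i})
        for i, seg in enumerate(segments)
    ]

    blades = {
        wing: kinematics.blade_element_states(
            cfg.wing_model(wing), wing_poses[wing], body_pose, cfg.hinges[wing]
        )
        for wing in WING_NAMES
    }
    truth_summaries = [
        kinematics.summarize_wingbeat(blades, wing_poses, body_pose, seg)
        for seg in segments
    ]

    return SyntheticFlight(
        config=cfg,
        trajectory=traj,
        body_pose=body_pose,
        wing_poses=wing_poses,
        reversal_events=events,
        segments=segments,
        truth_records=truth_records,
        truth_summaries=truth_summaries,
    )


# ---------------------------------------------------------------------------
# Camera rig and projection
# ---------------------------------------------------------------------------


def make_camera_rig(
    center=(0.15, 0.0, 0.12),
    distance: float = 1.0,
    focal_px: float = 1000.0,
    image_size: tuple[int, int] = (848, 480),
) -> list[CameraModel]:
    """Three orthogonally positioned pinhole cameras aimed at ``center``.

    One camera views along +y (side), one along -x (front) and one looks
    straight down, matching the layout of a three-camera flight tunnel rig.
    """
    c = np.asarray(center, dtype=float)
    pp = (image_size[0] / 2.0, image_size[1] / 2.0)
    return [
        CameraModel.look_at(c + [0.0, -distance, 0.0], c, focal_px=focal_px,
                            principal_point=pp, image_size=image_size),
        CameraModel.look_at(c + [distance, 0.0, 0.0], c, focal_px=focal_px,
                            principal_point=pp, image_size=image_size),
        CameraModel.look_at(c + [0.0, 0.0, distance], c, up=(0.0, 1.0, 0.0),
                            focal_px=focal_px, principal_point=pp, image_size=image_size),
    ]


@dataclass
class DigitizedViews:
    """Per-camera pixel tracks of the flight landmarks.

    ``pixels`` has shape (n_cameras, n_frames, n_landmarks, 2) with NaN for
    points behind a camera (flagged, never fabricated); ``visible`` is the
    matching boolean mask.
    """

    landmark_names: list[str]
    pixels: np.ndarray
    visible: np.ndarray
    frame_rate: float

    @property
    def n_cameras(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[1]

    def landmark_pixels(self, name: str) -> np.ndarray:
        """(n_cameras, n_frames, 2) pixel track of one landmark."""
        i = self.landmark_names.index(name)
        return self.pixels[:, :, i, :]

    def to_dataframe(self, camera: int) -> pd.DataFrame:
        rows = []
        for t in range(self.n_frames):
            for i, name in enumerate(self.landmark_names):
                vis = bool(self.visible[camera, t, i])
                u, v = self.pixels[camera, t, i]
                rows.append(
                    {
                        "frame": t,
                        "point_id": name,
                        "u_px": u if vis else "",
                        "v_px": v if vis else "",
                        "visible": int(vis),
                    }
                )
        return pd.DataFrame(rows)


def project_flight(
    flight: SyntheticFlight,
    cameras: list[CameraModel],
    pixel_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> DigitizedViews:
    """Project a synthetic flight's landmarks through a camera rig.

    Gaussian pixel noise of SD ``pixel_noise_sd`` is added to visible
    points; points behind a camera are flagged missing.
    """
    if len(cameras) < 2:
        raise ValueError("need at least two cameras for a stereo view")
    lm = flight.landmarks()
    names = list(lm.keys())
    n_frames = flight.n_frames
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pixels = np.full((len(cameras), n_frames, len(names), 2), np.nan)
    visible = np.zeros((len(cameras), n_frames, len(names)), dtype=bool)
    for ci, cam in enumerate(cameras):
        for li, name in enumerate(names):
            uv, ok = geometry.project(cam, lm[name])
            pixels[ci, :, li, :] = uv
            visible[ci, :, li] = ok
    if pixel_noise_sd > 0:
        noise = rng.normal(0.0, pixel_noise_sd, size=pixels.shape)
        pixels = pixels + noise
    pixels[~visible] = np.nan
    return DigitizedViews(
        landmark_names=names, pixels=pixels, visible=visible,
        frame_rate=flight.config.frame_rate,
    )


def generate_calibration_set(
    cameras: list[CameraModel],
    n_points: int = 40,
    volume=((-0.25, -0.25, -0.15), (0.55, 0.25, 0.45)),
    pixel_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_wand_pairs: int = 15,
    wand_length: float = 0.5,
) -> CalibrationPoints:
    """Random control points plus wand point-pairs of known separation.

    Emulates a wand-based field calibration: points span the working
    volume, and each wand pair is two points a fixed ``wand_length`` apart.
    Wand end-points are appended to the control points and referenced by
    index.  A coplanar point set triggers a degeneracy warning.
    """
    if n_points < 6:
        raise ValueError("need at least 6 control points per camera")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = np.asarray(volume[0], dtype=float)
    hi = np.asarray(volume[1], dtype=float)
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    wand_pairs = None
    if n_wand_pairs > 0:
        mids = rng.uniform(lo + wand_length / 2, hi - wand_length / 2, size=(n_wand_pairs, 3))
        dirs = rng.standard_normal((n_wand_pairs, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ends = np.concatenate(
            [mids - dirs * wand_length / 2.0, mids + dirs * wand_length / 2.0]
        )
        first = np.arange(n_wand_pairs) + n_points
        wand_pairs = np.column_stack([first, first + n_wand_pairs])
        pts = np.vstack([pts, ends])
    geometry.check_coplanarity(pts[:n_points])
    pixels = np.zeros((len(cameras), len(pts), 2))
    for ci, cam in enumerate(cameras):
        uv, ok = geometry.project(cam, pts)
        uv[~ok] = np.nan
        pixels[ci] = uv
    if pixel_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, pixel_noise_sd, size=pixels.shape)
    return CalibrationPoints(
        points3d=pts, pixels=pixels, wand_pairs=wand_pairs,
        wand_length=wand_length if n_wand_pairs > 0 else None,
    )


# ---------------------------------------------------------------------------
# Hierarchical cohorts
# ---------------------------------------------------------------------------


_DEFAULT_COUNTS = {
    "canopy": {"individuals_per_species": 5, "flights_per_individual": 4,
               "wingbeats_per_flight": 3},
    "understory": {"individuals_per_species": 3, "flights_per_individual": 3,
                   "wingbeats_per_flight": 2},
}

_DEFAULT_PARTITION = {"species": 0.15, "individual": 0.15, "flight": 0.15,
                      "wingbeat": 0.55}


def _default_group_params() -> dict:
    out = {}
    for summ in (CANOPY, UNDERSTORY):
        out[summ.microhabitat] = {
            "u_hor": summ.u_hor,
            "u_ver": summ.u_ver,
            "f_wingbeat": summ.f_wingbeat,
            "mass_g": summ.mass_g,
            "wing_area_cm2": summ.wing_area_cm2,
        }
    return out


@dataclass
class CohortDesign:
    """Design of a synthetic hierarchical cohort.

    ``group_params`` gives per-group (mean, SD) for each *base* metric;
    metrics not listed are, where possible, derived per wingbeat from the
    base draws (``u_total`` and ``gamma_climb`` from the horizontal and
    vertical speeds, distances as speed over wingbeat frequency), which
    induces the physical correlations among the eight wingbeat metrics.
    The SDs are total SDs across wingbeats, split across hierarchy levels
    by ``variance_partition`` (fractions summing to 1); species-level
    effects are correlated across species according to Brownian motion on
    ``tree``.  Morphology varies at the species and individual levels only.
    """

    group_species: dict = field(
        default_factory=lambda: {
            "canopy": list(CANOPY_SPECIES),
            "understory": list(UNDERSTORY_SPECIES),
        }
    )
    group_params: dict = field(default_factory=_default_group_params)
    counts: dict = field(default_factory=lambda: {g: dict(c) for g, c in _DEFAULT_COUNTS.items()})
    variance_partition: dict = field(default_factory=lambda: dict(_DEFAULT_PARTITION))
    tree: str = MORPHO_TREE
    seed: int = 0

    MORPHOLOGY_METRICS = ("mass_g", "wing_area_cm2")

    def __post_init__(self):
        fracs = np.array(list(self.variance_partition.values()), dtype=float)
        if np.any(fracs < 0):
            raise ValueError("variance fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        for g, params in self.group_params.items():
            for m, (mean, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"SD of {m} in group {g} is negative")
        for g, c in self.counts.items():
            if min(c.values()) < 1:
                raise ValueError("all counts must be at least 1")


@dataclass
class CohortDataset:
    """Tidy hierarchical tables of a (synthetic) cohort."""

    wingbeats: pd.DataFrame  # one row per wingbeat
    morphology: pd.DataFrame  # one row per individual
    tree: str
    design: CohortDesign | None = None


def _bm_species_effects(tree_str, species, sd, rng):
    """Species effects with BM correlation structure, scaled to SD ``sd``."""
    from .stats import tree_vcv

    tree = dendropy.Tree.get(data=tree_str, schema="newick")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tips]
    if missing:
        raise ValueError(f"tree tips do not match species names; missing {missing}")
    C = tree_vcv(tree, list(species))
    scale = np.sqrt(np.mean(np.diag(C)))
    L = np.linalg.cholesky(C / scale**2 + 1e-12 * np.eye(len(species)))
    z = L @ rng.standard_normal(len(species))
    return dict(zip(species, sd * z))


def generate_cohort(design: CohortDesign) -> CohortDataset:
    """Draw a hierarchical cohort from the multi-level Gaussian model.

    Each base metric of a wingbeat is
    ``group mean + species + individual + flight + wingbeat`` effects, the
    level SDs being the configured total SD split by the variance
    partition; species effects evolve under Brownian motion on the tree.
    Derived metrics (total speed, climb angle, per-wingbeat distances) are
    computed from the base draws.  Morphology (one row per individual) uses
    the species and individual variance shares only.
    """
    rng = np.random.default_rng(design.seed)
    part = design.variance_partition
    all_species = [s for g in design.group_species.values() for s in g]

    # per-metric species effects drawn once across the whole tree
    metric_names = sorted({m for p in design.group_params.values() for m in p})
    sp_eff = {}
    for m in metric_names:
        sds = [design.group_params[g][m][1] for g in design.group_params if m in design.group_params[g]]
        sd_m = float(np.mean(sds)) * np.sqrt(part.get("species", 0.0))
        sp_eff[m] = _bm_species_effects(design.tree, all_species, sd_m, rng)

    wb_rows = []
    morph_rows = []
    for group, species_list in design.group_species.items():
        params = design.group_params[group]
        c = design.counts[group]
        for sp in species_list:
            for ind_i in range(c["individuals_per_species"]):
                ind = f"{sp}_{ind_i + 1:02d}"
                ind_eff = {
                    m: rng.normal(0.0, params[m][1] * np.sqrt(part.get("individual", 0.0)))
                    for m in params
                }
                morph = {}
                for m in CohortDesign.MORPHOLOGY_METRICS:
                    if m in params:
                        mean, sd = params[m]
                        val = mean + sp_eff[m][sp] + ind_eff[m]
                        morph[m] = max(val, 0.05 * mean)  # keep physical
                morph_rows.append(
                    {"microhabitat": group, "species": sp, "individual": ind, **morph}
                )
                kin = [m for m in params if m not in CohortDesign.MORPHOLOGY_METRICS]
                for fl_i in range(c["flights_per_individual"]):
                    fl = f"{ind}_f{fl_i + 1}"
                    fl_eff = {
                        m: rng.normal(0.0, params[m][1] * np.sqrt(part.get("flight", 0.0)))
                        for m in kin
                    }
                    for wb_i in range(c["wingbeats_per_flight"]):
                        base = {}
                        for m in kin:
                            mean, sd = params[m]
                            e_wb = rng.normal(0.0, sd * np.sqrt(part.get("wingbeat", 0.0)))
                            base[m] = mean + sp_eff[m][sp] + ind_eff[m] + fl_eff[m] + e_wb
                        row = {
                            "microhabitat": group,
                            "species": sp,
                            "individual": ind,
                            "flight": fl,
                            "wingbeat_index": wb_i,
                        }
                        row.update(_derive_metrics(base))
                        wb_rows.append(row)

    wingbeats = pd.DataFrame(wb_rows)
    morphology = pd.DataFrame(morph_rows)
    return CohortDataset(wingbeats=wingbeats, morphology=morphology, tree=design.tree,
                         design=design)


def _derive_metrics(base: dict) -> dict:
    """Fill the eight wingbeat metrics from whichever base draws exist."""
    out = dict(base)
    if "u_hor" in out:
        out["u_hor"] = max(out["u_hor"], 0.05)  # horizontal speed magnitude
    if "f_wingbeat" in out:
        out["f_wingbeat"] = max(out["f_wingbeat"], 0.5)
    have = lambda *ms: all(m in out for m in ms)
    if have("u_hor", "u_ver"):
        out.setdefault("u_total", float(np.hypot(out["u_hor"], out["u_ver"])))
        out.setdefault(
            "gamma_climb", float(np.degrees(np.arctan2(out["u_ver"], out["u_hor"])))
        )
    if have("f_wingbeat"):
        f = out["f_wingbeat"]
        for u, dx in (("u_hor", "dx_hor"), ("u_ver", "dx_ver"), ("u_total", "dx_total")):
            if u in out:
                out.setdefault(dx, out[u] / f)
    for m in trajectory.METRIC_NAMES:
        out.setdefault(m, np.nan)
    return out


# ---------------------------------------------------------------------------
# Regression-shaped synthetic data
# ---------------------------------------------------------------------------


def generate_regression_sample(
    n: int,
    slope: float,
    intercept: float,
    x_mean: float,
    x_sd: float,
    r_squared: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (x, y) with a linear relation of prescribed population R^2.

    The residual SD is set to ``|slope| * x_sd * sqrt(1/R^2 - 1)`` so the
    population coefficient of determination equals ``r_squared``.
    """
    if not (0.0 < r_squared <= 1.0):
        raise ValueError("r_squared must lie in (0, 1]")
    if x_sd <= 0:
        raise ValueError("x_sd must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.normal(x_mean, x_sd, size=n)
    noise_sd = abs(slope) * x_sd * np.sqrt(1.0 / r_squared - 1.0)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    return x, y
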