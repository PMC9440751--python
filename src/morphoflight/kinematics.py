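"""Body orientation, stroke-plane wing Euler angles and blade-element states.

Conventions
-----------
World frame: right-handed, z up, gravity along -z.  Body frame: x along the
long axis toward the head, y toward the animal's left, z dorsal.  The body
orientation is the intrinsic Z(yaw)-Y(pitch)-X(roll) rotation with pitch
positive nose-up, so at pitch 90 deg the body axis points straight up.

The stroke plane of each wing is the plane normal to the body long axis
through that wing's hinge.  Wing posture relative to the stroke plane is
parameterized by three Euler angles:

* stroke angle ``phi``   -- sweep of the span axis within the stroke plane,
  zero at the lateral (horizontal-in-body) direction, positive dorsal;
* deviation angle ``theta`` -- elevation of the span axis out of the stroke
  plane, positive toward the head;
* rotation angle ``H``  -- pitch of the wing chord about the span axis,
  zero when the wing plane coincides with the stroke plane.

For the canonical left wing this is the rotation sequence
``R = Rx(phi) @ Rz(-theta) @ Ry(H)`` acting on the reference span axis
(body +y) and chord axis (body -z, the ventral reference direction).  Right
wings are handled by mirror conjugation through the body x-z plane, which
makes bilaterally symmetric strokes give mirrored stroke/deviation angles
and identical angles of attack by construction.

Blade elements: each rigid flat-plate wing is cut into 10 equal spanwise
strips; the local flow speed at each strip's area centroid is obtained by
finite-differencing the centroid's world position, and the angle of attack
is the angle between the wing plane and that velocity vector (always in
[0, 90] deg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon, box

__all__ = [
    "WING_NAMES",
    "BodyPose",
    "WingModel",
    "WingPoseSeries",
    "BladeElementSeries",
    "WingAngles",
    "WingbeatKinematicsSummary",
    "body_frame",
    "decompose_body_frame",
    "stroke_plane",
    "compose_wing_rotation",
    "wing_euler_angles",
    "blade_element_states",
    "summarize_wingbeat",
    "fit_rigid_orientation",
]

WING_NAMES = ("fore_left", "fore_right", "hind_left", "hind_right")

_MIRROR = np.diag([1.0, -1.0, 1.0])  # reflection through the body x-z plane

# reference wing basis in the body frame (left wing, all angles zero):
# span along +y (outboard), chord along -z (ventral), lying in the stroke plane
_SPAN0 = np.array([0.0, 1.0, 0.0])
_CHORD0 = np.array([0.0, 0.0, -1.0])


def _side(wing: str) -> str:
    if wing.endswith("left"):
        return "left"
    if wing.endswith("right"):
        return "right"
    raise ValueError(f"wing name {wing!r} must end in 'left' or 'right'")


class WingAngles(NamedTuple):
    """Stroke-plane Euler angles in degrees."""

    phi: float
    theta: float
    rotation: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Body orientation
# ---------------------------------------------------------------------------


def body_frame(yaw: float, pitch: float, roll: float, degrees: bool = True) -> np.ndarray:
    """World-from-body rotation matrix for intrinsic Z(yaw)-Y(pitch)-X(roll).

    Pitch is positive nose-up (about -y in the intermediate frame), so
    ``body_frame(0, 90, 0)`` maps the body x-axis to world +z.  Angles near
    gimbal lock (|pitch| > 89.9 deg) raise a warning but still return the
    (valid) rotation; only the yaw/roll split is ill-defined there.
    """
    for a in (yaw, pitch, roll):
        if not np.isfinite(a):
            raise ValueError("Euler angles must be finite")
    lim = 89.9 if degrees else np.radians(89.9)
    if abs(pitch) > lim:
        warnings.warn("pitch within 0.1 deg of gimbal lock; yaw/roll are poorly defined", stacklevel=2)
    return Rotation.from_euler("ZYX", [yaw, -pitch, roll], degrees=degrees).as_matrix()


def decompose_body_frame(R: np.ndarray, degrees: bool = True) -> tuple[float, float, float]:
    """Inverse of :func:`body_frame`: recover (yaw, pitch, roll)."""
    yaw, neg_pitch, roll = Rotation.from_matrix(R).as_euler("ZYX", degrees=degrees)
    return float(yaw), float(-neg_pitch), float(roll)


@dataclass
class BodyPose:
    """Per-frame body position and Euler angles (degrees)."""

    position: np.ndarray  # (n, 3) m
    yaw: np.ndarray  # (n,) deg
    pitch: np.ndarray  # (n,) deg
    roll: np.ndarray  # (n,) deg
    frame_rate: float

    def __post_init__(self):
        n = len(self.yaw)
        if self.position.shape != (n, 3) or len(self.pitch) != n or len(self.roll) != n:
            raise ValueError("inconsistent BodyPose array lengths")
        if np.any(np.abs(self.pitch) > 90.0 + 1e-9):
            raise ValueError("body pitch must lie in [-90, 90] deg")

    @property
    def n_frames(self) -> int:
        return len(self.yaw)

    def rotations(self) -> np.ndarray:
        """Stack of world-from-body rotation matrices, shape (n, 3, 3)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.stack(
                [body_frame(y, p, r) for y, p, r in zip(self.yaw, self.pitch, self.roll)]
            )

    def long_axis(self) -> np.ndarray:
        """Body long-axis unit vectors in the world frame, shape (n, 3)."""
        return self.rotations() @ np.array([1.0, 0.0, 0.0])


def stroke_plane(
    body_rotation: np.ndarray,
    body_position: np.ndarray,
    hinge_body: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Stroke plane of one wing: (point, unit normal) in world coordinates.

    The plane is normal to the body long axis and passes through the wing
    hinge, whose position is fixed in the body frame.
    """
    R = np.asarray(body_rotation, dtype=float)
    point = np.asarray(body_position, dtype=float) + R @ np.asarray(hinge_body, dtype=float)
    normal = R @ np.array([1.0, 0.0, 0.0])
    return point, normal


# ---------------------------------------------------------------------------
# Wing Euler angles
# ---------------------------------------------------------------------------


def compose_wing_rotation(phi: float, theta: float, rotation: float, side: str = "left",
                          degrees: bool = True) -> np.ndarray:
    """Body-frame rotation taking the reference wing pose to (phi, theta, H).

    The returned matrix maps wing-frame vectors (span = +y, chord = -z in
    the reference pose) into the body frame.  Right wings are the mirror
    conjugate of the left-wing composition.
    """
    if degrees:
        phi, theta, rotation = np.radians([phi, theta, rotation])
    Rx = Rotation.from_rotvec([phi, 0.0, 0.0]).as_matrix()
    Rz = Rotation.from_rotvec([0.0, 0.0, -theta]).as_matrix()
    Ry = Rotation.from_rotvec([0.0, rotation, 0.0]).as_matrix()
    R = Rx @ Rz @ Ry
    if side == "right":
        R = _MIRROR @ R @ _MIRROR
    elif side != "left":
        raise ValueError("side must be 'left' or 'right'")
    return R


def wing_euler_angles(R_wing_body: np.ndarray, side: str = "left") -> WingAngles:
    """Decompose a wing orientation (body frame) into (phi, theta, H), degrees.

    The span axis is the image of the reference outboard direction, the
    chord axis the image of the ventral reference.  When the span axis is
    parallel to the body long axis (theta = +/-90 deg) the stroke angle is
    undefined: it is returned as NaN with ``degenerate=True``.
    """
    R = np.asarray(R_wing_body, dtype=float)
    if side == "right":
        R = _MIRROR @ R @ _MIRROR
    elif side != "left":
        raise ValueError("side must be 'left' or 'right'")
    span = R @ _SPAN0
    sx = np.clip(span[0], -1.0, 1.0)
    theta = np.arcsin(sx)
    if 1.0 - abs(sx) < 1e-12:
        return WingAngles(phi=float("nan"), theta=float(np.degrees(theta)),
                          rotation=0.0, degenerate=True)
    phi = np.arctan2(span[2], span[1])
    # strip off phi and theta, leaving the pure span-axis rotation
    Rx = Rotation.from_rotvec([phi, 0.0, 0.0]).as_matrix()
    Rz = Rotation.from_rotvec([0.0, 0.0, -theta]).as_matrix()
    M = Rz.T @ Rx.T @ R
    H = np.arctan2(M[0, 2], M[2, 2])
    return WingAngles(
        phi=float(np.degrees(phi)),
        theta=float(np.degrees(theta)),
        rotation=float(np.degrees(H)),
        degenerate=False,
    )


@dataclass
class WingPoseSeries:
    """Per-frame stroke-plane Euler angles of one wing (degrees)."""

    wing: str
    phi: np.ndarray
    theta: np.ndarray
    rotation: np.ndarray
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return len(self.phi)

    @property
    def side(self) -> str:
        return _side(self.wing)

    def rotations(self) -> np.ndarray:
        """Body-frame wing rotation matrices recomposed from the angles."""
        return np.stack(
            [
                compose_wing_rotation(p, t, h, side=self.side)
                for p, t, h in zip(self.phi, self.theta, self.rotation)
            ]
        )

    def amplitude(self, start: int | None = None, end: int | None = None) -> float:
        """Stroke amplitude max(phi) - min(phi) over [start, end] frames."""
        sl = slice(start, None if end is None else end + 1)
        return float(np.max(self.phi[sl]) - np.min(self.phi[sl]))


# ---------------------------------------------------------------------------
# Wing model and blade elements
# ---------------------------------------------------------------------------


@dataclass
class WingModel:
    """Rigid flat-plate wing defined by a 41-point planar outline.

    Local frame: x spanwise from the hinge (at the origin) toward the tip,
    y chordwise.  Units are metres.
    """

    outline: np.ndarray  # (41, 2) m
    tip: np.ndarray | None = None  # defaults to the outline point of max x
    n_elements: int = 10

    def __post_init__(self):
        self.outline = np.asarray(self.outline, dtype=float)
        if self.outline.shape != (41, 2):
            raise ValueError(f"wing outline must have exactly 41 2D points, got {self.outline.shape}")
        if self.tip is None:
            self.tip = self.outline[np.argmax(self.outline[:, 0])].copy()
        self.tip = np.asarray(self.tip, dtype=float)
        if self.span <= 0:
            raise ValueError("wing span must be positive (tip must lie at x > 0)")
        self._polygon = Polygon(self.outline)
        if not self._polygon.is_valid:
            self._polygon = self._polygon.buffer(0)

    @property
    def span(self) -> float:
        return float(self.tip[0])

    @property
    def area(self) -> float:
        """Planform area of one wing, m^2."""
        return float(self._polygon.area)

    def element_centroids(self) -> np.ndarray:
        """Area centroids of the equal-span strips, local coords, (n_elements, 2)."""
        edges = np.linspace(0.0, self.span, self.n_elements + 1)
        cents = np.zeros((self.n_elements, 2))
        ymin, ymax = self.outline[:, 1].min() - 1.0, self.outline[:, 1].max() + 1.0
        for i in range(self.n_elements):
            strip = self._polygon.intersection(box(edges[i], ymin, edges[i + 1], ymax))
            if strip.is_empty or strip.area == 0.0:
                # a strip can be empty for concave outlines; fall back to the band midline
                cents[i] = [(edges[i] + edges[i + 1]) / 2.0, 0.0]
            else:
                c = strip.centroid
                cents[i] = [c.x, c.y]
        return cents

    def element_areas(self) -> np.ndarray:
        edges = np.linspace(0.0, self.span, self.n_elements + 1)
        ymin, ymax = self.outline[:, 1].min() - 1.0, self.outline[:, 1].max() + 1.0
        return np.array(
            [
                self._polygon.intersection(box(edges[i], ymin, edges[i + 1], ymax)).area
                for i in range(self.n_elements)
            ]
        )

    @classmethod
    def elliptical(cls, span: float, chord: float, n_elements: int = 10) -> "WingModel":
        """Synthetic elliptical planform with the hinge on the outline.

        Useful as a stand-in wing shape for simulation; area = pi*span*chord/4.
        """
        t = np.linspace(0.0, 2.0 * np.pi, 41, endpoint=False) + np.pi
        x = span / 2.0 + (span / 2.0) * np.cos(t)
        y = (chord / 2.0) * np.sin(t)
        return cls(outline=np.column_stack([x, y]), tip=np.array([span, 0.0]),
                   n_elements=n_elements)

    @classmethod
    def from_file(cls, path, n_elements: int = 10) -> "WingModel":
        """Read a 41-row, 2-column outline file (whitespace or comma separated)."""
        pts = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
        return cls(outline=pts, n_elements=n_elements)

    def to_file(self, path) -> None:
        np.savetxt(path, self.outline, fmt="%.9g")


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def _wing_basis_world(R_body: np.ndarray, R_wing_body: np.ndarray, side: str):
    """(span, chord, normal) unit vectors of a wing in the world frame."""
    span0 = _MIRROR @ _SPAN0 if side == "right" else _SPAN0
    chord0 = _MIRROR @ _CHORD0 if side == "right" else _CHORD0
    span = R_body @ (R_wing_body @ span0)
    chord = R_body @ (R_wing_body @ chord0)
    normal = np.cross(span, chord)
    return span, chord, normal


@dataclass
class BladeElementSeries:
    """Per-frame blade-element states of one wing."""

    wing: str
    positions: np.ndarray  # (n_frames, n_elements, 3) world m
    velocities: np.ndarray  # (n_frames, n_elements, 3) m/s
    speed: np.ndarray  # (n_frames, n_elements) m/s
    alpha: np.ndarray  # (n_frames, n_elements) deg, NaN where undefined
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_elements(self) -> int:
        return self.positions.shape[1]


def _central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends (axis 0)."""
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    v[0] = (x[1] - x[0]) / dt
    v[-1] = (x[-1] - x[-2]) / dt
    return v


def blade_element_states(
    wing_model: WingModel,
    wing_pose: WingPoseSeries,
    body_pose: BodyPose,
    hinge_body: np.ndarray,
    min_speed: float = 1e-9,
) -> BladeElementSeries:
    """Blade-element speeds and angles of attack for one wing.

    Element world positions combine the body pose, the fixed body-frame
    hinge and the wing orientation; velocities are central differences of
    those positions at the frame rate (one-sided at the series ends), so
    they include both body translation and wing rotation.  The angle of
    attack is the angle between the wing plane and the element velocity;
    samples with element speed below ``min_speed`` get NaN.
    """
    n = wing_pose.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames to difference velocities")
    if body_pose.n_frames != n:
        raise ValueError("wing pose and body pose must cover the same frames")
    side = wing_pose.side
    hinge_body = np.asarray(hinge_body, dtype=float)
    cents2d = wing_model.element_centroids()  # (k, 2) local
    k = len(cents2d)

    R_body = body_pose.rotations()
    R_wing = wing_pose.rotations()
    pos = np.zeros((n, k, 3))
    normals = np.zeros((n, 3))
    for t in range(n):
        span, chord, normal = _wing_basis_world(R_body[t], R_wing[t], side)
        origin = body_pose.position[t] + R_body[t] @ hinge_body
        pos[t] = origin + cents2d[:, [0]] * span + cents2d[:, [1]] * chord
        normals[t] = normal

    dt = 1.0 / wing_pose.frame_rate
    vel = _central_diff(pos, dt)
    speed = np.linalg.norm(vel, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_alpha = np.abs(np.einsum("tkc,tc->tk", vel, normals)) / speed
    alpha = np.degrees(np.arcsin(np.clip(sin_alpha, 0.0, 1.0)))
    alpha[speed < min_speed] = np.nan
    return BladeElementSeries(
        wing=wing_pose.wing,
        positions=pos,
        velocities=vel,
        speed=speed,
        alpha=alpha,
        frame_rate=wing_pose.frame_rate,
    )


# ---------------------------------------------------------------------------
# Wingbeat summary
# ---------------------------------------------------------------------------


@dataclass
class WingbeatKinematicsSummary:
    """Wingbeat-level kinematic summary.

    ``alpha_wingbeat`` is reported per wing pair (fore/hind): the
    blade-element mean angle of attack at the temporal midpoints of the
    downstroke and the upstroke, averaged over the two midpoints and the
    left/right wings.  ``u_wingbeat`` is the mean element speed over all
    elements of all four wings throughout the wingbeat; ``beta_wingbeat``
    the wingbeat-mean body pitch; ``amplitude`` the stroke amplitude
    max(phi) - min(phi) per pair.
    """

    alpha_fore: float  # deg
    alpha_hind: float  # deg
    u_wingbeat: float  # m/s
    beta_wingbeat: float  # deg
    amplitude_fore: float  # deg
    amplitude_hind: float  # deg
    used_nearest_valid_alpha: bool = False


def _mid_alpha(blades: BladeElementSeries, frame: int, lo: int, hi: int) -> tuple[float, bool]:
    """Blade-average alpha at ``frame``, falling back to the nearest frame in
    [lo, hi] with a defined value."""
    a = np.nanmean(blades.alpha[frame])
    if np.isfinite(a):
        return float(a), False
    order = sorted(range(lo, hi + 1), key=lambda f: (abs(f - frame), f))
    for f in order:
        a = np.nanmean(blades.alpha[f])
        if np.isfinite(a):
            return float(a), True
    return float("nan"), True


def summarize_wingbeat(
    blades: dict[str, BladeElementSeries],
    wing_poses: dict[str, WingPoseSeries],
    body_pose: BodyPose,
    segment,
) -> WingbeatKinematicsSummary:
    """Summarize one wingbeat's kinematics from the four wings' blade states.

    ``segment`` is a :class:`morphoflight.trajectory.WingbeatSegment` whose
    frame indices address the pose/blade series.
    """
    missing = [w for w in WING_NAMES if w not in blades or w not in wing_poses]
    if missing:
        raise ValueError(f"missing wings: {missing}")
    if segment.end >= body_pose.n_frames:
        raise ValueError("segment extends beyond the pose series")
    sl = slice(segment.start, segment.end + 1)
    mid_ds = (segment.start + segment.boundary) // 2
    mid_us = (segment.boundary + segment.end) // 2

    fallback = False
    alphas = {}
    for pair, wings in (("fore", ("fore_left", "fore_right")),
                        ("hind", ("hind_left", "hind_right"))):
        vals = []
        for w in wings:
            for mid, lo, hi in ((mid_ds, segment.start, segment.boundary),
                                (mid_us, segment.boundary, segment.end)):
                a, fb = _mid_alpha(blades[w], mid, lo, hi)
                fallback = fallback or fb
                vals.append(a)
        alphas[pair] = float(np.mean(vals))

    u = float(np.mean([blades[w].speed[sl] for w in WING_NAMES]))
    beta = float(np.mean(body_pose.pitch[sl]))
    amp = {
        pair: float(np.mean([wing_poses[w].amplitude(segment.start, segment.end)
                             for w in wings]))
        for pair, wings in (("fore", ("fore_left", "fore_right")),
                            ("hind", ("hind_left", "hind_right")))
    }
    return WingbeatKinematicsSummary(
        alpha_fore=alphas["fore"],
        alpha_hind=alphas["hind"],
        u_wingbeat=u,
        beta_wingbeat=beta,
        amplitude_fore=amp["fore"],
        amplitude_hind=amp["hind"],
        used_nearest_valid_alpha=fallback,
    )


# ---------------------------------------------------------------------------
# Pose recovery from reconstructed landmarks
# ---------------------------------------------------------------------------


def fit_rigid_orientation(local_planar: np.ndarray, world: np.ndarray,
                          origin_world: np.ndarray) -> np.ndarray:
    """Best-fit rotation mapping planar wing-local points to world points.

    ``local_planar`` (k, 2) are wing-model coordinates (span, chord) of
    landmarks whose reconstructed world positions are ``world`` (k, 3);
    ``origin_world`` is the reconstructed hinge.  Returns the 3x3 matrix
    whose columns are the world-frame span, chord and normal axes (Kabsch
    fit, proper rotation).
    """
    local = np.column_stack([local_planar, np.zeros(len(local_planar))])
    rot, _ = Rotation.align_vectors(np.asarray(world) - np.asarray(origin_world), local)
    return rot.as_matrix()


def body_pose_from_landmarks(
    head: np.ndarray,
    tail: np.ndarray,
    hinge_left: np.ndarray,
    hinge_right: np.ndarray,
    centroid: np.ndarray,
    frame_rate: float,
) -> BodyPose:
    """Recover the body pose series from reconstructed anatomical landmarks.

    The long axis comes from the head-tail line; the lateral axis from the
    left-right forewing hinge line, orthogonalized against the long axis.
    All arrays have shape (n, 3).
    """
    x = head - tail
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    yt = hinge_left - hinge_right
    y = yt - np.sum(yt * x, axis=1, keepdims=True) * x
    y = y / np.linalg.norm(y, axis=1, keepdims=True)
    z = np.cross(x, y)
    n = len(x)
    yaw = np.zeros(n)
    pitch = np.zeros(n)
    roll = np.zeros(n)
    for t in range(n):
        R = np.column_stack([x[t], y[t], z[t]])
        yaw[t], pitch[t], roll[t] = decompose_body_frame(R)
    return BodyPose(position=np.asarray(centroid, dtype=float), yaw=yaw, pitch=pitch,
                    roll=roll, frame_rate=frame_rate)
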