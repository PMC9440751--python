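"""Body-trajectory processing: Kalman smoothing, wingbeat segmentation and
per-wingbeat climb-performance metrics.

The smoother is a per-axis linear Kalman filter with a constant-acceleration
state model (state = position, velocity, acceleration) followed by a
Rauch-Tung-Striebel fixed-interval backward pass, the appropriate offline
estimator for digitized flight tracks.  Wingbeats are delimited by manually
digitized stroke reversals (highest upstroke position to the next one, so a
wingbeat is one downstroke followed by one upstroke), and each wingbeat is
summarized by eight climb metrics: wingbeat frequency, the horizontal /
vertical / total distance travelled, the corresponding wingbeat-mean speeds,
and the climb angle gamma = atan(U_ver / U_hor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SmoothedTrajectory",
    "WingbeatSegment",
    "WingbeatRecord",
    "EnsembleTrace",
    "kalman_smooth",
    "segment_wingbeats",
    "merge_reversals",
    "wingbeat_metrics",
    "ensemble_dynamics",
    "climb_angle",
]

#: per-wingbeat metric names, in canonical column order
METRIC_NAMES = (
    "f_wingbeat",
    "dx_hor",
    "dx_ver",
    "dx_total",
    "u_hor",
    "u_ver",
    "u_total",
    "gamma_climb",
)


@dataclass
class SmoothedTrajectory:
    """Per-frame body state after smoothing (SI units, world frame z-up)."""

    time: np.ndarray  # (n,) s
    position: np.ndarray  # (n, 3) m
    velocity: np.ndarray  # (n, 3) m/s
    acceleration: np.ndarray  # (n, 3) m/s^2
    frame_rate: float

    def __post_init__(self):
        n = len(self.time)
        for name in ("position", "velocity", "acceleration"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
        dt = np.diff(self.time)
        if len(dt) and not np.all(dt > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def u_hor(self) -> np.ndarray:
        """Horizontal speed magnitude per frame (non-negative)."""
        return np.hypot(self.velocity[:, 0], self.velocity[:, 1])

    @property
    def u_ver(self) -> np.ndarray:
        """Signed vertical velocity per frame (positive up)."""
        return self.velocity[:, 2]

    @property
    def u_total(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)

    @property
    def gamma_climb(self) -> np.ndarray:
        """Per-frame climb angle in degrees."""
        return np.degrees(np.arctan2(self.u_ver, self.u_hor))


@dataclass(frozen=True)
class WingbeatSegment:
    """One wingbeat: top reversal -> bottom reversal -> next top reversal."""

    start: int  # frame of the opening top reversal
    boundary: int  # frame of the downstroke/upstroke boundary (bottom reversal)
    end: int  # frame of the closing top reversal
    frame_rate: float

    def __post_init__(self):
        if not (self.start < self.boundary < self.end):
            raise ValueError(
                f"wingbeat frames must satisfy start < boundary < end, "
                f"got ({self.start}, {self.boundary}, {self.end})"
            )

    @property
    def dt_wingbeat(self) -> float:
        """Wingbeat duration in seconds."""
        return (self.end - self.start) / self.frame_rate

    @property
    def f_wingbeat(self) -> float:
        return 1.0 / self.dt_wingbeat


@dataclass
class WingbeatRecord:
    """Eight climb metrics of one wingbeat plus hierarchy labels."""

    f_wingbeat: float  # Hz
    dx_hor: float  # m, horizontal path length
    dx_ver: float  # m, net vertical displacement (signed)
    dx_total: float  # m, 3D path length
    u_hor: float  # m/s, wingbeat-mean horizontal speed
    u_ver: float  # m/s, wingbeat-mean vertical velocity
    u_total: float  # m/s, wingbeat-mean total speed
    gamma_climb: float  # deg
    microhabitat: str = ""
    species: str = ""
    individual: str = ""
    flight: str = ""
    wingbeat_index: int = 0

    def metrics(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def climb_angle(u_ver: float, u_hor: float) -> float:
    """Climb angle gamma = atan(U_ver / U_hor) in degrees, in [-90, 90].

    ``u_hor`` is a horizontal speed magnitude and therefore non-negative,
    which keeps the angle in the climbing/descending half-range.
    """
    if u_hor < 0:
        raise ValueError("u_hor is a speed magnitude and cannot be negative")
    return float(np.degrees(np.arctan2(u_ver, u_hor)))


# ---------------------------------------------------------------------------
# Kalman smoothing
# ---------------------------------------------------------------------------


def _ca_matrices(dt: float, q: float, r: float):
    F = np.array([[1.0, dt, 0.5 * dt**2], [0.0, 1.0, dt], [0.0, 0.0, 1.0]])
    # white-jerk (acceleration-rate) process noise with spectral density q
    Q = q * np.array(
        [
            [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
            [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
            [dt**3 / 6.0, dt**2 / 2.0, dt],
        ]
    )
    H = np.array([[1.0, 0.0, 0.0]])
    R = np.array([[r**2]])
    return F, Q, H, R


def _smooth_axis(z: np.ndarray, dt: float, q: float, r: float):
    """Forward Kalman filter + RTS smoother for one coordinate axis.

    ``z`` may contain NaN (missing frames): those steps are prediction-only.
    Returns (n, 3) smoothed states [p, v, a].
    """
    n = len(z)
    F, Q, H, R = _ca_matrices(dt, q, r)

    obs_idx = np.flatnonzero(np.isfinite(z))
    # initialize from the first up-to-three observations; exact for tracks with
    # constant acceleration, so a model-matched track is recovered identically
    i0, i1, i2 = (obs_idx[k] if k < len(obs_idx) else None for k in range(3))
    x0 = np.zeros(3)
    x0[0] = z[i0]
    if i2 is not None:
        t0, t1, t2 = i0 * dt, i1 * dt, i2 * dt
        # quadratic through three points, evaluated at t0
        denom = (t1 - t0) * (t2 - t0) * (t2 - t1)
        a2 = ((z[i2] - z[i0]) * (t1 - t0) - (z[i1] - z[i0]) * (t2 - t0)) / denom
        b1 = (z[i1] - z[i0]) / (t1 - t0) - a2 * (t1 + t0)
        x0[2] = 2.0 * a2
        x0[1] = b1 + 2.0 * a2 * t0
    elif i1 is not None:
        x0[1] = (z[i1] - z[i0]) / ((i1 - i0) * dt)
    P0 = np.diag([r**2, (2 * r / dt) ** 2, (4 * r / dt**2) ** 2]) * 10.0

    xp = np.zeros((n, 3))  # predicted means
    Pp = np.zeros((n, 3, 3))
    xf = np.zeros((n, 3))  # filtered means
    Pf = np.zeros((n, 3, 3))
    x, P = x0, P0
    for t in range(n):
        if t > i0:
            x = F @ x
            P = F @ P @ F.T + Q
        xp[t], Pp[t] = x, P
        if np.isfinite(z[t]):
            y = z[t] - H @ x
            S = H @ P @ H.T + R
            K = P @ H.T / S
            x = x + (K @ y).ravel()
            P = (np.eye(3) - K @ H) @ P
        xf[t], Pf[t] = x, P

    xs = np.zeros((n, 3))
    xs[-1] = xf[-1]
    Ps = Pf[-1]
    for t in range(n - 2, -1, -1):
        C = np.linalg.solve(Pp[t + 1].T, (Pf[t] @ F.T).T).T
        xs[t] = xf[t] + C @ (xs[t + 1] - xp[t + 1])
        Ps = Pf[t] + C @ (Ps - Pp[t + 1]) @ C.T
    return xs


def kalman_smooth(
    raw_track: np.ndarray,
    frame_rate: float,
    process_noise: float = 500.0,
    obs_noise: float = 2e-3,
    t0: float = 0.0,
) -> SmoothedTrajectory:
    """Smooth a raw 3D position track into position/velocity/acceleration.

    Parameters
    ----------
    raw_track : ndarray, shape (n, 3)
        Triangulated body-centroid positions in metres; NaN rows mark
        frames with no reconstruction (handled by prediction-only steps).
    frame_rate : float
        Hz; frames are assumed evenly spaced.
    process_noise : float
        Spectral density of the white jerk driving the constant-acceleration
        model, m^2 s^-5.  Larger values track manoeuvres more closely at the
        cost of less noise rejection.
    obs_noise : float
        Position observation noise SD in metres; sensible default is the
        triangulation residual of the rig.
    """
    z = np.asarray(raw_track, dtype=float)
    if z.ndim != 2 or z.shape[1] != 3:
        raise ValueError("raw_track must have shape (n, 3)")
    if len(z) < 5:
        raise ValueError("need at least 5 frames to smooth")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    observed = np.all(np.isfinite(z), axis=1)
    if not observed.any():
        raise ValueError("track contains no observed frames")
    # axes smoothed independently; treat a frame as missing on every axis
    # if any coordinate is missing (triangulation is all-or-nothing)
    z = z.copy()
    z[~observed] = np.nan

    dt = 1.0 / frame_rate
    states = np.stack([_smooth_axis(z[:, ax], dt, process_noise, obs_noise) for ax in range(3)])
    n = len(z)
    time = t0 + np.arange(n) * dt
    return SmoothedTrajectory(
        time=time,
        position=states[:, :, 0].T.copy(),
        velocity=states[:, :, 1].T.copy(),
        acceleration=states[:, :, 2].T.copy(),
        frame_rate=float(frame_rate),
    )


# ---------------------------------------------------------------------------
# Wingbeat segmentation and metrics
# ---------------------------------------------------------------------------


def merge_reversals(top_frames, bottom_frames) -> list[tuple[int, str]]:
    """Merge separately digitized top/bottom reversal frames into one
    chronologically sorted event list."""
    events = [(int(f), "top") for f in top_frames] + [(int(f), "bottom") for f in bottom_frames]
    return sorted(events)


def segment_wingbeats(
    reversal_events: list[tuple[int, str]],
    frame_rate: float,
) -> list[WingbeatSegment]:
    """Split a flight into wingbeats from digitized stroke reversals.

    ``reversal_events`` is a chronological list of ``(frame, kind)`` with
    kind ``"top"`` (highest upstroke position) or ``"bottom"`` (lowest
    downstroke position).  Events must alternate; each top-bottom-top triple
    yields one wingbeat (downstroke first).
    """
    if len(reversal_events) < 3:
        raise ValueError("need at least 3 reversal events for one wingbeat")
    frames = [int(f) for f, _ in reversal_events]
    kinds = [k for _, k in reversal_events]
    for k in kinds:
        if k not in ("top", "bottom"):
            raise ValueError(f"unknown reversal kind {k!r}")
    for i in range(1, len(kinds)):
        if kinds[i] == kinds[i - 1]:
            raise ValueError(
                f"reversal events must alternate top/bottom; event {i} "
                f"(frame {frames[i]}) repeats {kinds[i]!r}"
            )
        if frames[i] <= frames[i - 1]:
            raise ValueError(f"reversal frames must increase; event {i} does not")
    segments = []
    i = kinds.index("top")
    while i + 2 < len(frames):
        segments.append(
            WingbeatSegment(
                start=frames[i],
                boundary=frames[i + 1],
                end=frames[i + 2],
                frame_rate=frame_rate,
            )
        )
        i += 2
    if not segments:
        raise ValueError("no complete top-bottom-top wingbeat in the event list")
    return segments


def wingbeat_metrics(
    traj: SmoothedTrajectory,
    seg: WingbeatSegment,
    labels: dict | None = None,
) -> WingbeatRecord:
    """Compute the eight per-wingbeat climb metrics for one segment.

    Distances are path lengths over the segment (horizontal projection for
    ``dx_hor``, full 3D for ``dx_total``) except the signed net vertical
    displacement ``dx_ver``; speeds are wingbeat means of the per-frame
    smoothed velocity, and the climb angle applies atan to the
    wingbeat-mean vertical and horizontal speeds.
    """
    if seg.start < 0 or seg.end >= traj.n_frames:
        raise ValueError(
            f"segment frames [{seg.start}, {seg.end}] fall outside the "
            f"trajectory of {traj.n_frames} frames"
        )
    sl = slice(seg.start, seg.end + 1)
    pos = traj.position[sl]
    steps = np.diff(pos, axis=0)
    dx_hor = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))
    dx_total = float(np.sum(np.linalg.norm(steps, axis=1)))
    dx_ver = float(pos[-1, 2] - pos[0, 2])
    u_hor = float(np.mean(traj.u_hor[sl]))
    u_ver = float(np.mean(traj.u_ver[sl]))
    u_total = float(np.mean(traj.u_total[sl]))
    labels = labels or {}
    return WingbeatRecord(
        f_wingbeat=seg.f_wingbeat,
        dx_hor=dx_hor,
        dx_ver=dx_ver,
        dx_total=dx_total,
        u_hor=u_hor,
        u_ver=u_ver,
        u_total=u_total,
        gamma_climb=climb_angle(u_ver, u_hor),
        **labels,
    )


# ---------------------------------------------------------------------------
# Ensemble temporal dynamics
# ---------------------------------------------------------------------------


@dataclass
class EnsembleTrace:
    """Wingbeat-normalized ensemble mean of a per-frame metric.

    The time axis is normalized separately within downstroke and upstroke
    (phase fraction 0..1 in each), so wingbeats of different durations can
    be averaged pointwise.
    """

    phase: np.ndarray  # "DS" / "US" per grid point
    fraction: np.ndarray  # 0..1 within the stroke phase
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_wingbeats: int
    ci_defined: bool


def _resample_phase(series, a, b, n):
    src = np.arange(a, b + 1, dtype=float)
    grid = a + (b - a) * np.linspace(0.0, 1.0, n)
    return np.interp(grid, src, series[a : b + 1])


def ensemble_dynamics(
    series: np.ndarray,
    segments: list[WingbeatSegment],
    n_samples_per_phase: int = 50,
    confidence: float = 0.95,
) -> EnsembleTrace:
    """Average a per-frame metric across wingbeats on a normalized time grid.

    Each wingbeat's downstroke and upstroke are linearly resampled to
    ``n_samples_per_phase`` points; the trace carries the pointwise mean and
    a Student-t confidence interval across wingbeats.  With a single
    wingbeat the mean is returned and the CI flagged undefined.
    """
    series = np.asarray(series, dtype=float)
    if not segments:
        raise ValueError("no wingbeat segments supplied")
    rows = []
    for seg in segments:
        if seg.end >= len(series):
            raise ValueError("segment extends beyond the metric series")
        ds = _resample_phase(series, seg.start, seg.boundary, n_samples_per_phase)
        us = _resample_phase(series, seg.boundary, seg.end, n_samples_per_phase)
        rows.append(np.concatenate([ds, us]))
    M = np.vstack(rows)
    k = len(rows)
    mean = M.mean(axis=0)
    frac = np.tile(np.linspace(0.0, 1.0, n_samples_per_phase), 2)
    phase = np.array(["DS"] * n_samples_per_phase + ["US"] * n_samples_per_phase)
    if k >= 2:
        sem = M.std(axis=0, ddof=1) / np.sqrt(k)
        tcrit = sps.t.ppf(0.5 + confidence / 2.0, df=k - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
        defined = True
    else:
        lo = np.full_like(mean, np.nan)
        hi = np.full_like(mean, np.nan)
        defined = False
    return EnsembleTrace(
        phase=phase,
        fraction=frac,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        n_wingbeats=k,
        ci_defined=defined,
    )
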