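"""Direct linear transformation (DLT) camera calibration and stereo triangulation.

The 11-parameter DLT maps a world point ``(x, y, z)`` in metres to a pixel
``(u, v)``::

    u = (L1 x + L2 y + L3 z + L4)  / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8)  / (L9 x + L10 y + L11 z + 1)

This is the classic linear pinhole model used throughout animal biomechanics
(DLTdv / easyWand conventions).  Lens distortion is assumed to have been
removed upstream; all geometry here is linear.  Calibration solves the
homogeneous least-squares problem by SVD with Hartley-style coordinate
pre-normalization, and triangulation is the linear (algebraic) least-squares
solution over all cameras that see a point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "CalibrationPoints",
    "Reconstruction3D",
    "estimate_dlt",
    "project",
    "triangulate",
    "triangulate_track",
    "wand_check",
    "WandCheckResult",
]

#: minimum number of 3D-2D correspondences for an 11-parameter solution
MIN_CALIBRATION_POINTS = 6


class DegenerateCalibrationError(ValueError):
    """Raised when the calibration point set cannot constrain all 11 coefficients."""


@dataclass(frozen=True)
class CameraModel:
    """An 11-coefficient DLT camera.

    Parameters
    ----------
    L : ndarray, shape (11,)
        DLT coefficients, constant (12th) coefficient fixed at 1.
    image_size : tuple of int, optional
        (width, height) in pixels; used only for field-of-view checks.
    front_sign : {+1, -1}
        Sign of the projection denominator for points in front of the
        camera.  Set at construction/calibration time; a projected point
        whose denominator has the opposite sign lies behind the camera.
    """

    L: np.ndarray
    image_size: tuple[int, int] | None = None
    front_sign: int = 1

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        if L.shape != (11,):
            raise ValueError(f"DLT coefficient vector must have shape (11,), got {L.shape}")
        if not np.all(np.isfinite(L)):
            raise ValueError("DLT coefficients must be finite")
        object.__setattr__(self, "L", L)

    # -- convenience -------------------------------------------------------
    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 homogeneous projection matrix (last entry 1)."""
        L = self.L
        return np.array(
            [
                [L[0], L[1], L[2], L[3]],
                [L[4], L[5], L[6], L[7]],
                [L[8], L[9], L[10], 1.0],
            ]
        )

    def project(self, points3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points; see :func:`project`."""
        return project(self, points3d)

    @classmethod
    def from_pinhole(
        cls,
        focal_px: float,
        principal_point: tuple[float, float],
        R: np.ndarray,
        center: np.ndarray,
        image_size: tuple[int, int] | None = None,
    ) -> "CameraModel":
        """Build DLT coefficients from an ideal pinhole camera.

        ``R`` maps world vectors into the camera frame (rows are the camera
        axes; third row is the viewing direction), ``center`` is the camera
        position in world coordinates.
        """
        R = np.asarray(R, dtype=float)
        center = np.asarray(center, dtype=float)
        K = np.array(
            [
                [focal_px, 0.0, principal_point[0]],
                [0.0, focal_px, principal_point[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        P = K @ np.hstack([R, (-R @ center)[:, None]])
        scale = P[2, 3]
        if scale == 0.0:
            raise ValueError("world origin lies on the camera's principal plane; shift the rig")
        front_sign = 1 if scale > 0 else -1
        P = P / scale
        L = np.concatenate([P[0], P[1], P[2, :3]])
        return cls(L=L, image_size=image_size, front_sign=front_sign)

    @classmethod
    def look_at(
        cls,
        center: np.ndarray,
        target: np.ndarray,
        up: np.ndarray = (0.0, 0.0, 1.0),
        focal_px: float = 1000.0,
        principal_point: tuple[float, float] = (424.0, 240.0),
        image_size: tuple[int, int] | None = (848, 480),
    ) -> "CameraModel":
        """Pinhole camera at ``center`` looking toward ``target``."""
        center = np.asarray(center, dtype=float)
        z = np.asarray(target, dtype=float) - center
        nz = np.linalg.norm(z)
        if nz == 0:
            raise ValueError("camera center and target coincide")
        z = z / nz
        up = np.asarray(up, dtype=float)
        x = np.cross(z, up)
        if np.linalg.norm(x) < 1e-12:  # viewing along 'up': pick another reference
            x = np.cross(z, np.array([1.0, 0.0, 0.0]))
        x = x / np.linalg.norm(x)
        y = np.cross(z, x)
        R = np.vstack([x, y, z])
        return cls.from_pinhole(focal_px, principal_point, R, center, image_size)


# Backwards-friendly alias matching the field's "DLT coefficients" jargon.
DLTCoefficients = CameraModel


@dataclass
class CalibrationPoints:
    """Known 3D control points with per-camera pixel observations.

    ``pixels`` has shape (n_cameras, n_points, 2); NaN marks a point not
    seen by a camera.  ``wand_pairs`` is an (m, 2) integer array of point
    indices whose true 3D separation is ``wand_length`` metres (the moving
    wand of field calibrations).
    """

    points3d: np.ndarray
    pixels: np.ndarray
    wand_pairs: np.ndarray | None = None
    wand_length: float | None = None

    def __post_init__(self):
        self.points3d = np.asarray(self.points3d, dtype=float)
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.points3d.ndim != 2 or self.points3d.shape[1] != 3:
            raise ValueError("points3d must have shape (n, 3)")
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 2:
            raise ValueError("pixels must have shape (n_cameras, n_points, 2)")
        if self.pixels.shape[1] != self.points3d.shape[0]:
            raise ValueError("pixel and 3D point counts disagree")


@dataclass
class Reconstruction3D:
    """Triangulated 3D points with per-point diagnostics."""

    points3d: np.ndarray  # (n, 3); NaN rows are unreconstructable frames
    reprojection_rmse: np.ndarray  # (n,) pixels, NaN where missing
    n_cameras: np.ndarray  # (n,) contributing camera count

    @property
    def valid(self) -> np.ndarray:
        return self.n_cameras >= 2


def _normalize_3d(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform taking points to zero centroid, RMS radius sqrt(3)."""
    c = X.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((X - c) ** 2, axis=1)))
    s = np.sqrt(3.0) / rms if rms > 0 else 1.0
    T = np.diag([s, s, s, 1.0])
    T[:3, 3] = -s * c
    Xh = np.hstack([X, np.ones((len(X), 1))])
    return (T @ Xh.T).T, T


def _normalize_2d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = x.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum((x - c) ** 2, axis=1)))
    s = np.sqrt(2.0) / rms if rms > 0 else 1.0
    T = np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])
    xh = np.hstack([x, np.ones((len(x), 1))])
    return (T @ xh.T).T, T


def estimate_dlt(
    points3d: np.ndarray,
    pixels: np.ndarray,
    image_size: tuple[int, int] | None = None,
) -> tuple[CameraModel, float]:
    """Calibrate one camera from 3D-2D correspondences.

    Solves the homogeneous DLT system by SVD after Hartley pre-normalization
    of both coordinate sets, then rescales so the constant coefficient is 1.

    Returns
    -------
    camera : CameraModel
    rmse : float
        Reprojection root-mean-square error over the calibration points, px.

    Raises
    ------
    DegenerateCalibrationError
        For fewer than 6 points or a (near-)coplanar point cloud, which
        leaves the 11 coefficients underdetermined.
    """
    X = np.asarray(points3d, dtype=float)
    x = np.asarray(pixels, dtype=float)
    ok = np.all(np.isfinite(x), axis=1) & np.all(np.isfinite(X), axis=1)
    X, x = X[ok], x[ok]
    n = len(X)
    if n < MIN_CALIBRATION_POINTS:
        raise DegenerateCalibrationError(
            f"DLT calibration needs at least {MIN_CALIBRATION_POINTS} points, got {n}"
        )
    # coplanarity check on the centered 3D cloud
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateCalibrationError(
            "calibration points are coplanar (rank-deficient DLT design matrix); "
            "spread control points through the volume"
        )

    Xn, T3 = _normalize_3d(X)
    xn, T2 = _normalize_2d(x)
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xn
    A[0::2, 8:12] = -xn[:, [0]] * Xn
    A[1::2, 4:8] = Xn
    A[1::2, 8:12] = -xn[:, [1]] * Xn
    _, _, Vt = np.linalg.svd(A)
    P = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T2) @ P @ T3
    if abs(P[2, 3]) < 1e-12 * np.abs(P).max():
        raise DegenerateCalibrationError("estimated camera has zero constant coefficient")
    P = P / P[2, 3]
    L = np.concatenate([P[0], P[1], P[2, :3]])
    # denominator sign at the calibration points decides the in-front convention
    D = X @ L[8:11] + 1.0
    front_sign = 1 if np.median(np.sign(D)) >= 0 else -1
    cam = CameraModel(L=L, image_size=image_size, front_sign=front_sign)
    uv, _ = project(cam, X)
    rmse = float(np.sqrt(np.mean(np.sum((uv - x) ** 2, axis=1))))
    return cam, rmse


def project(camera: CameraModel, points3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project world points through a DLT camera.

    Returns
    -------
    pixels : ndarray, shape (..., 2)
        Pixel coordinates; NaN where the projection is invalid.
    valid : ndarray of bool
        False where the point lies behind the camera or on its principal
        plane (zero denominator).
    """
    X = np.asarray(points3d, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("points must be finite")
    L = camera.L
    D = X @ L[8:11] + 1.0
    valid = camera.front_sign * D > 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X @ L[0:3] + L[3]) / D
        v = (X @ L[4:7] + L[7]) / D
    uv = np.stack([u, v], axis=-1)
    uv[~valid] = np.nan
    if single:
        return uv[0], valid[0]
    return uv, valid


def triangulate(
    cameras: list[CameraModel],
    pixels_per_camera: np.ndarray,
) -> tuple[np.ndarray, float, int]:
    """Triangulate a single point from >= 2 camera views.

    ``pixels_per_camera`` has shape (n_cameras, 2); NaN marks a camera that
    does not see the point.  Returns the linear least-squares 3D solution,
    its reprojection RMSE (px) and the number of contributing cameras.
    A point visible in fewer than two views returns NaN coordinates.
    """
    if len(cameras) == 0:
        raise ValueError("no cameras supplied")
    uv = np.asarray(pixels_per_camera, dtype=float)
    if uv.shape != (len(cameras), 2):
        raise ValueError("pixels_per_camera must have shape (n_cameras, 2)")
    rows = []
    rhs = []
    used = []
    for i, (cam, p) in enumerate(zip(cameras, uv)):
        if not np.all(np.isfinite(p)):
            continue
        L = cam.L
        u, v = p
        rows.append(L[0:3] - u * L[8:11])
        rhs.append(u - L[3])
        rows.append(L[4:7] - v * L[8:11])
        rhs.append(v - L[7])
        used.append(i)
    if len(used) < 2:
        return np.full(3, np.nan), float("nan"), len(used)
    A = np.asarray(rows)
    b = np.asarray(rhs)
    X, *_ = np.linalg.lstsq(A, b, rcond=None)
    errs = []
    for i in used:
        puv, ok = project(cameras[i], X)
        if ok:
            errs.append(np.sum((puv - uv[i]) ** 2))
    rmse = float(np.sqrt(np.mean(errs))) if errs else float("nan")
    return X, rmse, len(used)


def triangulate_track(
    cameras: list[CameraModel],
    pixels: np.ndarray,
) -> Reconstruction3D:
    """Triangulate a whole track.

    ``pixels`` has shape (n_cameras, n_frames, 2), NaN for missing
    observations.  Frames with fewer than two views come back as NaN rows
    rather than being fabricated.
    """
    if len(cameras) < 2:
        raise ValueError("triangulation requires at least two cameras")
    uv = np.asarray(pixels, dtype=float)
    n_frames = uv.shape[1]
    pts = np.full((n_frames, 3), np.nan)
    rmse = np.full(n_frames, np.nan)
    ncams = np.zeros(n_frames, dtype=int)
    for t in range(n_frames):
        pts[t], rmse[t], ncams[t] = triangulate(cameras, uv[:, t, :])
    return Reconstruction3D(points3d=pts, reprojection_rmse=rmse, n_cameras=ncams)


@dataclass
class WandCheckResult:
    """Reconstructed-minus-known wand length statistics (metres)."""

    errors: np.ndarray
    mean_error: float
    sd_error: float
    known_length: float

    @property
    def n_pairs(self) -> int:
        return len(self.errors)


def wand_check(
    cameras: list[CameraModel],
    wand_pixel_pairs: np.ndarray,
    known_length: float,
) -> WandCheckResult:
    """Reconstruct wand end-points and compare pair distances to the known length.

    ``wand_pixel_pairs`` has shape (n_pairs, 2 ends, n_cameras, 2).  This is
    the standard sanity check of a wand calibration: with good coefficients
    the reconstructed separations match the physical wand.
    """
    pairs = np.asarray(wand_pixel_pairs, dtype=float)
    if pairs.ndim != 4 or pairs.shape[1] != 2 or pairs.shape[3] != 2:
        raise ValueError("wand_pixel_pairs must have shape (n_pairs, 2, n_cameras, 2)")
    errors = []
    for pair in pairs:
        a, _, na = triangulate(cameras, pair[0])
        b, _, nb = triangulate(cameras, pair[1])
        if na >= 2 and nb >= 2:
            errors.append(np.linalg.norm(a - b) - known_length)
    if not errors:
        raise ValueError("no wand pair could be reconstructed from >= 2 views")
    errors = np.asarray(errors)
    return WandCheckResult(
        errors=errors,
        mean_error=float(errors.mean()),
        sd_error=float(errors.std(ddof=1)) if len(errors) > 1 else 0.0,
        known_length=float(known_length),
    )


def check_coplanarity(points3d: np.ndarray, tol: float = 1e-9) -> bool:
    """Return True (and warn) if a 3D point cloud is coplanar to tolerance."""
    X = np.asarray(points3d, dtype=float)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    coplanar = bool(sv[2] < tol * max(sv[0], 1.0))
    if coplanar:
        warnings.warn(
            "calibration points are coplanar; the DLT design matrix is rank-deficient",
            stacklevel=2,
        )
    return coplanar
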