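"""Pinhole camera geometry shared by every stage of the fusion pipeline.

A camera is modelled as an ideal pinhole with Brown-Conrady lens distortion:
a 3D point ``(X, Y, Z)`` in the camera frame maps to normalized image
coordinates ``(x, y) = (X/Z, Y/Z)``, the distortion model warps those, and
the intrinsic matrix scales to pixels::

    u = fx * x_d + u0
    v = fy * y_d + v0

with radial terms ``1 + k1 r^2 + k2 r^4 + k3 r^6`` (``r^2 = x^2 + y^2``) and
tangential terms ``2 p1 x y + p2 (r^2 + 2 x^2)`` /
``p1 (r^2 + 2 y^2) + 2 p2 x y``.

Rigid transforms between sensor frames are carried as a Rodrigues rotation
vector plus a translation in meters, matching the convention of standard
pose solvers.

The module also hosts the time-of-flight phase-to-distance relation, the one
piece of sensor physics the pipeline relies on: a ToF camera measures the
phase shift ``phi`` of a modulated signal of wavelength ``lam`` and the
object distance is ``d = phi / (2 pi) * lam / 2`` (the light travels the
distance twice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import BehindCameraError, InvalidInputError, InvalidParameterError

__all__ = [
    "CameraModel",
    "Pose",
    "PhaseMeasurement",
    "phase_to_distance",
    "distort_normalized",
    "undistort_normalized",
    "project_point",
    "project_points",
    "undistort_image",
    "undistort_pixels",
    "rodrigues",
    "rotation_to_rvec",
    "load_intrinsics",
    "save_intrinsics",
    "round_half_away",
]


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer with halves away from zero (raster writes)."""
    x = np.asarray(x)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass(frozen=True)
class CameraModel:
    """Intrinsics and distortion of one camera.

    Parameters
    ----------
    fx, fy : float
        Focal lengths in pixels.
    u0, v0 : float
        Principal point in pixels (0-based, origin top-left).
    width, height : int
        Sensor size in pixels.
    k1, k2, k3 : float
        Radial distortion coefficients (dimensionless).
    p1, p2 : float
        Tangential distortion coefficients (dimensionless).
    name : str
        Free-form camera identifier (e.g. ``"thermal"``).
    """

    fx: float
    fy: float
    u0: float
    v0: float
    width: int
    height: int
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    name: str = "camera"

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise InvalidParameterError("focal lengths must be positive")
        if not (int(self.width) > 0 and int(self.height) > 0):
            raise InvalidParameterError("sensor size must be positive")
        if not (0 <= self.u0 < self.width and 0 <= self.v0 < self.height):
            raise InvalidParameterError("principal point must lie on the sensor")

    @property
    def shape(self) -> tuple[int, int]:
        """Image array shape ``(height, width)``."""
        return (self.height, self.width)

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix."""
        return np.array(
            [[self.fx, 0.0, self.u0], [0.0, self.fy, self.v0], [0.0, 0.0, 1.0]]
        )

    @property
    def distortion(self) -> np.ndarray:
        """Distortion coefficients in ``[k1, k2, p1, p2, k3]`` order."""
        return np.array([self.k1, self.k2, self.p1, self.p2, self.k3])

    def has_distortion(self) -> bool:
        return bool(np.any(self.distortion != 0.0))


@dataclass
class Pose:
    """Rigid transform from a source frame (ToF) into a camera frame.

    ``X_cam = R @ X_src + t`` with ``R = rodrigues(rvec)``.
    """

    rvec: np.ndarray
    tvec: np.ndarray
    _R: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.rvec = np.asarray(self.rvec, dtype=float).reshape(3)
        self.tvec = np.asarray(self.tvec, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.rvec)) and np.all(np.isfinite(self.tvec))):
            raise InvalidParameterError("pose parameters must be finite")

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.zeros(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, R: np.ndarray, t: np.ndarray) -> "Pose":
        return cls(rotation_to_rvec(R), np.asarray(t, dtype=float).reshape(3))

    @property
    def R(self) -> np.ndarray:
        if self._R is None:
            self._R = rodrigues(self.rvec)
        return self._R

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform ``(..., 3)`` points into the camera frame."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.R.T + self.tvec

    def inverse(self) -> "Pose":
        R_inv = self.R.T
        return Pose.from_matrix(R_inv, -R_inv @ self.tvec)

    def compose(self, other: "Pose") -> "Pose":
        """Return the pose applying ``other`` first, then ``self``."""
        R = self.R @ other.R
        t = self.R @ other.tvec + self.tvec
        return Pose.from_matrix(R, t)


@dataclass(frozen=True)
class PhaseMeasurement:
    """One ToF phase reading: phase shift ``phi`` (rad) of a modulated signal
    with wavelength ``lam`` (m)."""

    phi: float
    lam: float

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise InvalidParameterError("phase shift must be non-negative")
        if self.lam <= 0:
            raise InvalidParameterError("modulation wavelength must be positive")


def phase_to_distance(m: PhaseMeasurement) -> float:
    """Distance (m) from a ToF phase measurement: ``phi/(2 pi) * lam/2``.

    The modulated signal travels to the object and back, hence the factor
    ``lam / 2``; a full-cycle phase shift corresponds to half a wavelength
    of one-way distance (the unambiguous range).
    """
    return (m.phi / (2.0 * np.pi)) * (m.lam / 2.0)


def rodrigues(rvec: np.ndarray) -> np.ndarray:
    """Axis-angle rotation vector -> 3x3 rotation matrix."""
    rvec = np.asarray(rvec, dtype=float).reshape(3)
    if not np.all(np.isfinite(rvec)):
        raise InvalidParameterError("rotation vector must be finite")
    return Rotation.from_rotvec(rvec).as_matrix()


def rotation_to_rvec(R: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix -> axis-angle rotation vector (inverse of rodrigues)."""
    return Rotation.from_matrix(np.asarray(R, dtype=float)).as_rotvec()


def distort_normalized(
    x: np.ndarray | float, y: np.ndarray | float, cam: CameraModel
) -> tuple[np.ndarray, np.ndarray]:
    """Apply Brown-Conrady distortion to normalized image coordinates.

    Total function; the on-axis point (0, 0) is a fixed point for any
    coefficient setting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r2 = x * x + y * y
    radial = 1.0 + r2 * (cam.k1 + r2 * (cam.k2 + r2 * cam.k3))
    x_d = x * radial + 2.0 * cam.p1 * x * y + cam.p2 * (r2 + 2.0 * x * x)
    y_d = y * radial + cam.p1 * (r2 + 2.0 * y * y) + 2.0 * cam.p2 * x * y
    return x_d, y_d


def undistort_normalized(
    x_d: np.ndarray | float,
    y_d: np.ndarray | float,
    cam: CameraModel,
    *,
    n_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the distortion model by fixed-point iteration.

    Converges quickly for the moderate distortion of real lenses; with zero
    coefficients it is the identity after one iteration.
    """
    x_d = np.asarray(x_d, dtype=float)
    y_d = np.asarray(y_d, dtype=float)
    x, y = x_d.copy(), y_d.copy()
    for _ in range(n_iter):
        r2 = x * x + y * y
        radial = 1.0 + r2 * (cam.k1 + r2 * (cam.k2 + r2 * cam.k3))
        dx = 2.0 * cam.p1 * x * y + cam.p2 * (r2 + 2.0 * x * x)
        dy = cam.p1 * (r2 + 2.0 * y * y) + 2.0 * cam.p2 * x * y
        x = (x_d - dx) / radial
        y = (y_d - dy) / radial
    return x, y


def project_points(
    points: np.ndarray,
    pose: Pose,
    cam: CameraModel,
    *,
    apply_distortion: bool = True,
    allow_behind: bool = False,
) -> np.ndarray:
    """Project ``(n, 3)`` points (source frame) to ``(n, 2)`` pixel coordinates.

    Parameters
    ----------
    allow_behind : bool
        When False (default) any transformed point with ``Z <= 0`` raises
        :class:`BehindCameraError`. When True such points yield NaN pixels
        instead, which suits dense cloud projection where off-frustum points
        are expected and simply skipped.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3:
        raise InvalidInputError("points must have shape (n, 3)")
    cam_pts = pose.apply(pts)
    z = cam_pts[:, 2]
    behind = z <= 0
    if np.any(behind):
        if not allow_behind:
            raise BehindCameraError(
                f"{int(behind.sum())} point(s) have non-positive depth"
            )
        z = np.where(behind, np.nan, z)
    x = cam_pts[:, 0] / z
    y = cam_pts[:, 1] / z
    if apply_distortion and cam.has_distortion():
        x, y = distort_normalized(x, y, cam)
    uv = np.stack([cam.fx * x + cam.u0, cam.fy * y + cam.v0], axis=-1)
    return uv


def project_point(
    point: np.ndarray,
    pose: Pose,
    cam: CameraModel,
    *,
    apply_distortion: bool = True,
) -> np.ndarray:
    """Project a single 3D point; raises if it lies behind the camera."""
    return project_points(
        np.asarray(point, dtype=float).reshape(1, 3),
        pose,
        cam,
        apply_distortion=apply_distortion,
    )[0]


def undistort_pixels(uv: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Map distorted pixel coordinates to their undistorted positions."""
    uv = np.atleast_2d(np.asarray(uv, dtype=float))
    x_d = (uv[:, 0] - cam.u0) / cam.fx
    y_d = (uv[:, 1] - cam.v0) / cam.fy
    x, y = undistort_normalized(x_d, y_d, cam)
    return np.stack([cam.fx * x + cam.u0, cam.fy * y + cam.v0], axis=-1)


def undistort_image(img: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Rectify a full image (inverse warp with bilinear interpolation).

    Each output (rectified) pixel is sampled from the input at the location
    the lens would have imaged it to; samples falling outside the source
    are filled black, producing the familiar dark rectification border.
    With all coefficients zero the output equals the input exactly.
    """
    img = np.asarray(img)
    if img.shape[0] != cam.height or img.shape[1] != cam.width:
        raise InvalidInputError(
            f"image shape {img.shape[:2]} does not match camera "
            f"({cam.height}, {cam.width})"
        )
    if not cam.has_distortion():
        return img.copy()
    vv, uu = np.meshgrid(
        np.arange(cam.height, dtype=float),
        np.arange(cam.width, dtype=float),
        indexing="ij",
    )
    x = (uu - cam.u0) / cam.fx
    y = (vv - cam.v0) / cam.fy
    x_d, y_d = distort_normalized(x, y, cam)
    src_u = cam.fx * x_d + cam.u0
    src_v = cam.fy * y_d + cam.v0
    coords = np.stack([src_v.ravel(), src_u.ravel()])

    def warp_channel(ch: np.ndarray) -> np.ndarray:
        out = ndimage.map_coordinates(
            ch.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        return out.reshape(cam.height, cam.width)

    if img.ndim == 2:
        out = warp_channel(img)
    else:
        out = np.stack([warp_channel(img[..., c]) for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def load_intrinsics(path) -> CameraModel:
    """Read a per-camera intrinsics YAML file.

    Expected keys: ``camera_name, width, height, fx, fy, u0, v0,
    distortion`` where ``distortion`` is ``[k1, k2, p1, p2]`` or
    ``[k1, k2, p1, p2, k3]`` (missing ``k3`` is taken as zero).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    dist = list(data.get("distortion", [0.0, 0.0, 0.0, 0.0, 0.0]))
    if len(dist) == 4:
        dist = dist + [0.0]
    if len(dist) != 5:
        raise InvalidInputError("distortion must list 4 or 5 coefficients")
    k1, k2, p1, p2, k3 = (float(c) for c in dist)
    return CameraModel(
        fx=float(data["fx"]),
        fy=float(data["fy"]),
        u0=float(data["u0"]),
        v0=float(data["v0"]),
        width=int(data["width"]),
        height=int(data["height"]),
        k1=k1,
        k2=k2,
        k3=k3,
        p1=p1,
        p2=p2,
        name=str(data.get("camera_name", "camera")),
    )


def save_intrinsics(cam: CameraModel, path) -> None:
    """Write the intrinsics YAML consumed by :func:`load_intrinsics`."""
    data = {
        "camera_name": cam.name,
        "width": int(cam.width),
        "height": int(cam.height),
        "fx": float(cam.fx),
        "fy": float(cam.fy),
        "u0": float(cam.u0),
        "v0": float(cam.v0),
        "distortion": [float(c) for c in (cam.k1, cam.k2, cam.p1, cam.p2, cam.k3)],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
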