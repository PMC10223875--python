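"""Extrinsic calibration of a 2D camera against the ToF camera.

Given correspondences between 3D points in the ToF frame and their pixel
projections in a target camera (thermal or RGB), the rigid pose of that
camera relative to the ToF sensor is recovered by perspective-n-point:

1. image points are undistorted, keeping the linear stage linear;
2. an initial pose comes from the Direct Linear Transform — the full 3x4
   projection DLT for general point sets, or a plane-to-image homography
   decomposition when the points are coplanar (a circle-grid target always
   is, and the 12-parameter DLT is rank-deficient for it);
3. the pose is refined by Levenberg-Marquardt on the reprojection residuals
   of the full distorted model.

The solver is deterministic given a fixed input order; there is no random
sampling. An optional one-shot outlier rejection (drop residuals above
3x the median, re-solve once) is available for hand-curated sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import yaml
from scipy.optimize import least_squares

from .camera import (
    CameraModel,
    Pose,
    project_points,
    rotation_to_rvec,
    undistort_normalized,
)
from .errors import (
    CalibrationFailedError,
    DegenerateConfigurationError,
    InsufficientCorrespondencesError,
)
from .pointcloud import OrganizedPointCloud
from .targets import (
    BlobDetectorConfig,
    CorrespondenceSet,
    GridSpec,
    build_correspondences,
    detect_blobs,
    order_grid,
)

__all__ = [
    "CalibrationResult",
    "solve_pnp",
    "reprojection_rmse",
    "calibrate_pair",
    "save_calibration",
    "load_calibration",
]

MIN_CORRESPONDENCES = 6
_PLANARITY_RTOL = 1e-4  # smallest/largest singular value ratio below -> planar


@dataclass
class CalibrationResult:
    """Solved extrinsic pose plus its reprojection quality."""

    pose: Pose
    rmse: float
    n_used: int
    modality: str = "unknown"


def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: zero centroid, mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.linalg.norm(pts - c, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    h = np.hstack([pts, np.ones((pts.shape[0], 1))])
    return (h @ T.T)[:, :2], T


def _homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography mapping 2D ``src`` to 2D ``dst`` (both inhomogeneous)."""
    n = src.shape[0]
    src_n, Ts = _normalize_2d(src)
    dst_n, Td = _normalize_2d(dst)
    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    u, v = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0], A[0::2, 1], A[0::2, 2] = x, y, 1.0
    A[0::2, 6], A[0::2, 7], A[0::2, 8] = -u * x, -u * y, -u
    A[1::2, 3], A[1::2, 4], A[1::2, 5] = x, y, 1.0
    A[1::2, 6], A[1::2, 7], A[1::2, 8] = -v * x, -v * y, -v
    _, s, vt = np.linalg.svd(A)
    if s[-2] <= 1e-12 * s[0]:
        raise DegenerateConfigurationError("homography system is rank-deficient")
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _pose_from_planar(obj: np.ndarray, xy: np.ndarray) -> Pose:
    """Initial pose from coplanar 3D points via homography decomposition.

    ``xy`` are undistorted normalized image coordinates, so the homography
    from in-plane coordinates to the image is ``s [r1 r2 t]``.
    """
    centroid = obj.mean(axis=0)
    _, _, vt = np.linalg.svd(obj - centroid)
    e1, e2 = vt[0], vt[1]
    plane_coords = (obj - centroid) @ np.stack([e1, e2], axis=1)
    H = _homography(plane_coords, xy)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 2.0 / (np.linalg.norm(h1) + np.linalg.norm(h2))
    r1, r2, t = lam * h1, lam * h2, lam * h3
    if t[2] < 0:  # plane must lie in front of the camera
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R_approx = np.stack([r1, r2, r3], axis=1)
    # project onto SO(3)
    U, _, Vt = np.linalg.svd(R_approx)
    R_p = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    # compose plane->camera with ToF->plane: X_cam = R_p E^T (X - c) + t
    E_T = np.stack([e1, e2, np.cross(e1, e2)], axis=0)
    R = R_p @ E_T
    tvec = t - R @ centroid
    return Pose.from_matrix(R, tvec)


def _pose_from_dlt(obj: np.ndarray, xy: np.ndarray) -> Pose:
    """Initial pose from a general 3D point set via the 3x4 projection DLT."""
    n = obj.shape[0]
    c3 = obj.mean(axis=0)
    scale3 = np.linalg.norm(obj - c3, axis=1).mean()
    s3 = np.sqrt(3.0) / scale3 if scale3 > 0 else 1.0
    obj_n = (obj - c3) * s3
    xy_n, T2 = _normalize_2d(xy)
    A = np.zeros((2 * n, 12))
    X = np.hstack([obj_n, np.ones((n, 1))])
    u, v = xy_n[:, 0], xy_n[:, 1]
    A[0::2, 0:4] = X
    A[0::2, 8:12] = -u[:, None] * X
    A[1::2, 4:8] = X
    A[1::2, 8:12] = -v[:, None] * X
    _, s, vt = np.linalg.svd(A)
    if s[-2] <= 1e-9 * s[0]:
        raise DegenerateConfigurationError(
            "DLT system is rank-deficient (degenerate or coplanar geometry)"
        )
    P = vt[-1].reshape(3, 4)
    # undo normalizations: x_norm = T2 x, X_norm = s3 (X - c3)
    S = np.eye(4) * s3
    S[3, 3] = 1.0
    S[:3, 3] = -s3 * c3
    P = np.linalg.inv(T2) @ P @ S
    M = P[:, :3]
    if np.linalg.det(M) < 0:
        P = -P
        M = -M
    scale = np.linalg.det(M) ** (1.0 / 3.0)
    M /= scale
    U, _, Vt = np.linalg.svd(M)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    t = P[:, 3] / scale
    return Pose.from_matrix(R, t)


def _refine(pose: Pose, corr: CorrespondenceSet, cam: CameraModel) -> Pose:
    obj = corr.object_points
    img = corr.image_points

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = Pose(theta[:3], theta[3:])
        uv = project_points(obj, p, cam, apply_distortion=True, allow_behind=True)
        res = (uv - img).ravel()
        return np.nan_to_num(res, nan=1e6)

    theta0 = np.concatenate([pose.rvec, pose.tvec])
    sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    return Pose(sol.x[:3], sol.x[3:])


def solve_pnp(
    corr: CorrespondenceSet,
    cam: CameraModel,
    *,
    reject_outliers: bool = False,
) -> Pose:
    """Recover the camera pose from 3D-2D correspondences (PnP).

    DLT (or planar homography) initialization followed by LM refinement
    over the rotation vector and translation. Deterministic for a fixed
    input order. With ``reject_outliers`` the solve is repeated once after
    dropping correspondences whose residual exceeds 3x the median.
    """
    if len(corr) < MIN_CORRESPONDENCES:
        raise InsufficientCorrespondencesError(
            f"{len(corr)} correspondences; PnP needs >= {MIN_CORRESPONDENCES}"
        )
    obj = corr.object_points
    # undistort the observed pixels -> ideal normalized coordinates
    x_d = (corr.image_points[:, 0] - cam.u0) / cam.fx
    y_d = (corr.image_points[:, 1] - cam.v0) / cam.fy
    x, y = undistort_normalized(x_d, y_d, cam)
    xy = np.stack([x, y], axis=1)

    centered = obj - obj.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    planar = sv[-1] <= _PLANARITY_RTOL * sv[0]
    pose0 = _pose_from_planar(obj, xy) if planar else _pose_from_dlt(obj, xy)
    pose = _refine(pose0, corr, cam)

    if reject_outliers:
        uv = project_points(
            obj, pose, cam, apply_distortion=True, allow_behind=True
        )
        res = np.linalg.norm(uv - corr.image_points, axis=1)
        med = np.median(res)
        keep = res <= 3.0 * med if med > 0 else np.ones(len(corr), bool)
        if keep.sum() >= MIN_CORRESPONDENCES and keep.sum() < len(corr):
            sub = CorrespondenceSet(
                obj[keep], corr.image_points[keep], modality=corr.modality
            )
            pose = _refine(pose, sub, cam)
    return pose


def reprojection_rmse(
    corr: CorrespondenceSet, pose: Pose, cam: CameraModel
) -> float:
    """Root mean square of Euclidean pixel residuals under ``pose``.

    Zero iff every projection is exact; a behind-camera point propagates
    as an error rather than being silently ignored.
    """
    uv = project_points(corr.object_points, pose, cam, apply_distortion=True)
    res2 = np.sum((uv - corr.image_points) ** 2, axis=1)
    return float(np.sqrt(res2.mean()))


def calibrate_pair(
    tof_frames,
    cam_frames,
    cloud: OrganizedPointCloud | list[OrganizedPointCloud],
    spec: GridSpec,
    cam: CameraModel,
    *,
    modality: str = "unknown",
    tof_blob_config: BlobDetectorConfig | None = None,
    cam_blob_config: BlobDetectorConfig | None = None,
) -> CalibrationResult:
    """Full extrinsic calibration from raw frame pairs.

    For every (ToF mono, camera) frame pair the circle grid is detected in
    both images, ordered row-major, and converted into 3D-2D pairs through
    the organized cloud of that frame. Pairs from all usable frames are
    pooled into one PnP solve; the pooled reprojection RMSE and the number
    of correspondences used are reported. Frames where either grid cannot
    be completed are skipped; if no frame survives, calibration fails.
    """
    def as_gray(img):
        img = np.asarray(img)
        return img.mean(axis=2) if img.ndim == 3 else img

    clouds = cloud if isinstance(cloud, (list, tuple)) else [cloud] * len(tof_frames)
    all_obj, all_img = [], []
    for tof_img, cam_img, cl in zip(tof_frames, cam_frames, clouds):
        try:
            tof_kps = detect_blobs(as_gray(tof_img), tof_blob_config)
            cam_kps = detect_blobs(as_gray(cam_img), cam_blob_config)
            tof_centers = order_grid(tof_kps, spec)
            cam_centers = order_grid(cam_kps, spec)
            corr = build_correspondences(
                tof_centers, cam_centers, cl, modality=modality
            )
        except Exception:
            continue
        all_obj.append(corr.object_points)
        all_img.append(corr.image_points)
    if not all_obj:
        raise CalibrationFailedError("no frame pair yielded a complete grid")
    pooled = CorrespondenceSet(
        np.vstack(all_obj), np.vstack(all_img), modality=modality
    )
    pose = solve_pnp(pooled, cam)
    rmse = reprojection_rmse(pooled, pose, cam)
    return CalibrationResult(pose=pose, rmse=rmse, n_used=len(pooled), modality=modality)


def save_calibration(result: CalibrationResult, path) -> None:
    """Serialize a calibration result to YAML."""
    data = {
        "modality": result.modality,
        "rvec": [float(x) for x in result.pose.rvec],
        "tvec": [float(x) for x in result.pose.tvec],
        "rmse": float(result.rmse),
        "n_used": int(result.n_used),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_calibration(path) -> CalibrationResult:
    """Read a calibration YAML written by :func:`save_calibration`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CalibrationResult(
        pose=Pose(np.array(data["rvec"], float), np.array(data["tvec"], float)),
        rmse=float(data["rmse"]),
        n_used=int(data["n_used"]),
        modality=str(data.get("modality", "unknown")),
    )
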