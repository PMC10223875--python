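"""Thermal-RGB fusion through the ToF point cloud, and label projection.

Once the thermal and RGB cameras are extrinsically calibrated against the
ToF sensor, every ToF point can be projected into both images. The fusion
image lives on the thermal pixel grid: for each finite cloud point whose
projections land inside both frames, the RGB color at its RGB projection is
written at its thermal projection. Because the ToF sensor has far fewer
pixels than the thermal camera, the colored pixels are sparse; a provenance
mask records exactly which pixels carry RGB information.

The same bridge transfers annotations between modalities: the destination
box of a source-frame box is the envelope of the destination projections of
all cloud points whose source projection falls inside it. This only works
where the region of interest is supported by the cloud — a box over a cloud
hole raises :class:`~tofusion.errors.RoiOutsideCloudError`. Labeling one
modality and projecting to the other two is what makes the fusion approach
data-efficient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import BBox
from .camera import CameraModel, Pose, project_points, round_half_away
from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NotCalibratedError,
    RoiOutsideCloudError,
)
from .pointcloud import OrganizedPointCloud

__all__ = [
    "FusionFrame",
    "fuse_frame",
    "project_bbox",
    "labeling_efficiency",
    "write_fusion",
]

# provenance codes
PROV_THERMAL = 0
PROV_RGB = 1
PROV_DILATED = 2


@dataclass
class FusionFrame:
    """Fusion result on the thermal pixel grid.

    ``image`` is a 3-channel uint8 canvas the size of the thermal frame;
    ``provenance`` marks each pixel as thermal-only (0), RGB-colored (1) or
    filled by dilation (2); ``contributor`` holds the flat cloud index of
    the point that colored each pixel (-1 where none).
    """

    image: np.ndarray
    provenance: np.ndarray
    contributor: np.ndarray
    sources: dict = field(default_factory=dict)

    @property
    def colored_mask(self) -> np.ndarray:
        return self.provenance == PROV_RGB


def _to_rgb_canvas(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    elif img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError("thermal frame must be single- or 3-channel")
    if img.dtype != np.uint8:
        img = np.clip(np.rint(img.astype(float)), 0, 255).astype(np.uint8)
    return img.copy()


def fuse_frame(
    cloud: OrganizedPointCloud,
    rgb_frame: np.ndarray,
    thermal_frame: np.ndarray,
    pose_rgb: Pose | None,
    pose_thermal: Pose | None,
    cam_rgb: CameraModel,
    cam_thermal: CameraModel,
    *,
    dilate: bool = False,
    sources: dict | None = None,
) -> FusionFrame:
    """Synthesize the fusion image from one registered frame triple.

    Frames are assumed undistorted (projection is pure pinhole here). Each
    finite cloud point is projected into both cameras; if both projections
    are in-bounds, the nearest-pixel RGB sample is written at the nearest
    thermal pixel. When several points collide on one thermal pixel the one
    nearest the thermal camera wins (crude occlusion handling). With
    ``dilate`` the sparse colored pixels are grown by a 3x3 dilation into
    uncolored neighbors (marked separately in the provenance mask).
    """
    if pose_rgb is None or pose_thermal is None:
        raise NotCalibratedError("both RGB and thermal poses are required")
    rgb_frame = np.asarray(rgb_frame)
    if rgb_frame.shape[:2] != (cam_rgb.height, cam_rgb.width) or rgb_frame.ndim != 3:
        raise InvalidInputError("RGB frame does not match its camera model")
    thermal = np.asarray(thermal_frame)
    if thermal.shape[:2] != (cam_thermal.height, cam_thermal.width):
        raise InvalidInputError("thermal frame does not match its camera model")

    canvas = _to_rgb_canvas(thermal)
    H, W = cam_thermal.height, cam_thermal.width
    provenance = np.full((H, W), PROV_THERMAL, dtype=np.uint8)
    contributor = np.full((H, W), -1, dtype=np.int64)

    pts = cloud.flat()
    finite = np.all(np.isfinite(pts), axis=1)
    idx = np.nonzero(finite)[0]
    if idx.size:
        P = pts[idx]
        uv_t = project_points(
            P, pose_thermal, cam_thermal, apply_distortion=False, allow_behind=True
        )
        uv_c = project_points(
            P, pose_rgb, cam_rgb, apply_distortion=False, allow_behind=True
        )
        z_t = pose_thermal.apply(P)[:, 2]
        ut = round_half_away(uv_t[:, 0])
        vt = round_half_away(uv_t[:, 1])
        uc = round_half_away(uv_c[:, 0])
        vc = round_half_away(uv_c[:, 1])
        ok = (
            np.all(np.isfinite(uv_t), axis=1)
            & np.all(np.isfinite(uv_c), axis=1)
            & (ut >= 0) & (ut < W) & (vt >= 0) & (vt < H)
            & (uc >= 0) & (uc < cam_rgb.width) & (vc >= 0) & (vc < cam_rgb.height)
            & (z_t > 0)
        )
        ut, vt, uc, vc = ut[ok], vt[ok], uc[ok], vc[ok]
        z_ok = z_t[ok]
        src_idx = idx[ok]
        # nearest point wins per thermal pixel: process in decreasing depth,
        # later (nearer) writes overwrite farther ones
        order = np.argsort(-z_ok, kind="stable")
        ut, vt, uc, vc, src_idx = (
            ut[order], vt[order], uc[order], vc[order], src_idx[order]
        )
        canvas[vt, ut] = rgb_frame[vc, uc, :3]
        provenance[vt, ut] = PROV_RGB
        contributor[vt, ut] = src_idx

    if dilate:
        from scipy import ndimage

        colored = provenance == PROV_RGB
        grown = ndimage.binary_dilation(colored, np.ones((3, 3), bool))
        new = grown & ~colored
        for c in range(3):
            filled = ndimage.grey_dilation(
                np.where(colored, canvas[..., c], 0), footprint=np.ones((3, 3))
            )
            canvas[..., c][new] = filled[new]
        provenance[new] = PROV_DILATED

    return FusionFrame(
        image=canvas,
        provenance=provenance,
        contributor=contributor,
        sources=dict(sources or {}),
    )


def project_bbox(
    box: BBox,
    cloud: OrganizedPointCloud,
    pose_src: Pose,
    pose_dst: Pose,
    cam_src: CameraModel,
    cam_dst: CameraModel,
) -> BBox:
    """Transfer a box between modalities through the ToF cloud.

    All finite cloud points are projected into the source camera; those
    landing inside the box are projected into the destination camera and
    their axis-aligned envelope, clipped to the destination frame, is the
    transferred box. Requires at least one supporting cloud point.
    """
    pts = cloud.flat()
    finite = np.all(np.isfinite(pts), axis=1)
    P = pts[finite]
    if P.shape[0] == 0:
        raise RoiOutsideCloudError("point cloud holds no finite points")
    uv_src = project_points(
        P, pose_src, cam_src, apply_distortion=False, allow_behind=True
    )
    inside = (
        np.all(np.isfinite(uv_src), axis=1)
        & (uv_src[:, 0] >= box.x_min) & (uv_src[:, 0] <= box.x_max)
        & (uv_src[:, 1] >= box.y_min) & (uv_src[:, 1] <= box.y_max)
    )
    if not np.any(inside):
        raise RoiOutsideCloudError(
            "no ToF point projects inside the box; the ROI must lie within "
            "the point cloud for cross-modality transfer"
        )
    uv_dst = project_points(
        P[inside], pose_dst, cam_dst, apply_distortion=False, allow_behind=True
    )
    uv_dst = uv_dst[np.all(np.isfinite(uv_dst), axis=1)]
    if uv_dst.shape[0] == 0:
        raise RoiOutsideCloudError("supporting points fall behind the destination camera")
    out = BBox(
        label=box.label,
        x_min=float(uv_dst[:, 0].min()),
        y_min=float(uv_dst[:, 1].min()),
        x_max=float(uv_dst[:, 0].max()),
        y_max=float(uv_dst[:, 1].max()),
        confidence=box.confidence,
    )
    clipped = out.clipped(cam_dst.width, cam_dst.height)
    if clipped is None:
        raise RoiOutsideCloudError("transferred box falls outside the destination frame")
    return clipped


def labeling_efficiency(n_modalities: int, n_manual: int) -> int:
    """Percentage of labeling work saved by cross-modality projection.

    Labeling ``n_manual`` of ``n_modalities`` registered streams by hand
    and projecting the labels to the rest saves
    ``floor(100 * (n_modalities - n_manual) / n_modalities)`` percent.
    With three modalities and one manual set this is 66%.
    """
    if n_modalities < 1 or n_manual < 1 or n_manual > n_modalities:
        raise InvalidParameterError("require 1 <= n_manual <= n_modalities")
    return math.floor(100 * (n_modalities - n_manual) / n_modalities)


def write_fusion(frame: FusionFrame, out_dir, stem: str = "fusion") -> None:
    """Write fusion PNG + provenance mask PNG + JSON metadata."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{stem}.png", frame.image)
    mask = np.where(frame.provenance != PROV_THERMAL, 255, 0).astype(np.uint8)
    iio.imwrite(out / f"{stem}_provenance.png", mask)
    (out / f"{stem}.json").write_text(json.dumps(frame.sources, indent=1))
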