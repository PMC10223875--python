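"""Synthetic three-camera rig with exact ground truth.

Renders two kinds of scenes into registered thermal / RGB / ToF views with
known extrinsics, organized point clouds and labels:

* the circle calibration target (6 x 20 holes, 1 cm diameter, 13.96 mm
  pitch) on a flat board, for exercising detection and extrinsic
  calibration; and
* a neonate-like phantom — head and torso ellipsoids plus a protruding
  nose — with distinct thermal levels and RGB colors per body part, for
  exercising fusion and cross-modality label transfer.

The default rig mirrors the physical sensors: thermal 640x480 with a
90x64 degree field of view, ToF 224x171 with 62x45 degrees and a 0.1-4 m
range. Focal lengths are derived from those fields of view via
``fx = (width/2) / tan(fov_h/2)``. The RGB camera (1146x716) is given a
75-degree pinhole field of view: the physical fisheye optics are outside
the pinhole model, and a plausible pinhole stand-in is what the geometry
tests need.

Rendering is analytic ray-plane / ray-ellipsoid intersection with a
z-buffer and supersampled anti-aliasing — not photorealism, but pixel
positions, point clouds and silhouette boxes are exact, which is what the
downstream modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .annotations import BBox, write_coco_json, write_yolo_txt
from .camera import CameraModel, Pose, project_points, rodrigues, save_intrinsics
from .errors import VisibilityError
from .pointcloud import OrganizedPointCloud, write_pcd
from .targets import CorrespondenceSet, GridSpec

__all__ = [
    "RigConfig",
    "PhantomSpec",
    "default_rig",
    "default_phantom",
    "make_target_pose",
    "render_calibration_scene",
    "calibration_correspondences",
    "render_phantom_scene",
    "write_scene",
    "CalibrationScene",
    "PhantomScene",
    "PART_COLORS",
    "PART_THERMAL",
]


def _fov_camera(name: str, width: int, height: int,
                fov_h_deg: float, fov_v_deg: float) -> CameraModel:
    fx = (width / 2.0) / np.tan(np.radians(fov_h_deg) / 2.0)
    fy = (height / 2.0) / np.tan(np.radians(fov_v_deg) / 2.0)
    return CameraModel(
        fx=fx, fy=fy, u0=(width - 1) / 2.0, v0=(height - 1) / 2.0,
        width=width, height=height, name=name,
    )


@dataclass
class RigConfig:
    """Three camera models plus the true extrinsics of the 2D cameras.

    Poses map ToF-frame points into the thermal / RGB camera frames.
    """

    thermal: CameraModel
    rgb: CameraModel
    tof: CameraModel
    pose_thermal: Pose
    pose_rgb: Pose
    tof_range: tuple[float, float] = (0.1, 4.0)


def default_rig() -> RigConfig:
    """Rig with the physical resolutions/FoVs and a plausible baseline.

    The 2D cameras sit a few centimeters to either side of the ToF sensor,
    toed in slightly — the compact bracket geometry of a shared camera
    mount over an incubator.
    """
    return RigConfig(
        thermal=_fov_camera("thermal", 640, 480, 90.0, 64.0),
        rgb=_fov_camera("rgb", 1146, 716, 75.0, 51.0),
        tof=_fov_camera("tof", 224, 171, 62.0, 45.0),
        pose_thermal=Pose(np.array([0.01, -0.04, 0.005]),
                          np.array([0.045, 0.004, 0.002])),
        pose_rgb=Pose(np.array([-0.008, 0.05, -0.004]),
                      np.array([-0.055, 0.006, 0.003])),
    )


def make_target_pose(
    spec: GridSpec,
    distance: float = 0.45,
    rvec: np.ndarray | tuple = (0.0, 0.0, 0.0),
) -> Pose:
    """Pose placing the grid center on the ToF optical axis at ``distance``.

    ``rvec`` tilts/rolls the board about its center before placement.
    """
    R = rodrigues(np.asarray(rvec, float))
    center = np.array(
        [(spec.cols - 1) * spec.pitch / 2.0,
         (spec.rows - 1) * spec.pitch / 2.0, 0.0]
    )
    t = np.array([0.0, 0.0, distance]) - R @ center
    return Pose.from_matrix(R, t)


def _pixel_rays(cam: CameraModel, supersample: int = 1) -> np.ndarray:
    """(H*ss, W*ss, 3) unnormalized ray directions through (sub)pixels."""
    ss = supersample
    us = (np.arange(cam.width * ss) + 0.5) / ss - 0.5
    vs = (np.arange(cam.height * ss) + 0.5) / ss - 0.5
    uu, vv = np.meshgrid(us, vs)
    x = (uu - cam.u0) / cam.fx
    y = (vv - cam.v0) / cam.fy
    return np.stack([x, y, np.ones_like(x)], axis=-1)


def _downsample(img: np.ndarray, ss: int) -> np.ndarray:
    if ss == 1:
        return img
    H, W = img.shape[0] // ss, img.shape[1] // ss
    if img.ndim == 2:
        return img.reshape(H, ss, W, ss).mean(axis=(1, 3))
    return img.reshape(H, ss, W, ss, img.shape[2]).mean(axis=(1, 3))


@dataclass
class CalibrationScene:
    """Rendered calibration-target triple with full ground truth."""

    images: dict  # modality -> image array
    cloud: OrganizedPointCloud
    centers_3d: np.ndarray  # (rows*cols, 3) circle centers, ToF frame
    gt_centers: dict  # modality -> (rows*cols, 2) row-major pixel centers
    rig: RigConfig
    spec: GridSpec
    target_pose: Pose


def _render_target_view(
    cam: CameraModel,
    cam_from_tof: Pose,
    target_pose: Pose,
    spec: GridSpec,
    levels: tuple[float, float, float],
    supersample: int,
) -> np.ndarray:
    """Render the board seen by one camera (levels: background, board, hole)."""
    bg, board, hole = levels
    cam_from_target = cam_from_tof.compose(target_pose)
    R, t = cam_from_target.R, cam_from_target.tvec
    origin, e1, e2 = t, R[:, 0], R[:, 1]
    n = R[:, 2]
    rays = _pixel_rays(cam, supersample)
    denom = rays @ n
    s = (origin @ n) / np.where(np.abs(denom) < 1e-12, np.nan, denom)
    q = rays * s[..., None]
    rel = q - origin
    a = rel @ e1
    b = rel @ e2
    margin = spec.pitch
    on_board = (
        (s > 0)
        & (a >= -margin) & (a <= (spec.cols - 1) * spec.pitch + margin)
        & (b >= -margin) & (b <= (spec.rows - 1) * spec.pitch + margin)
    )
    j = np.clip(np.round(a / spec.pitch), 0, spec.cols - 1)
    i = np.clip(np.round(b / spec.pitch), 0, spec.rows - 1)
    d2 = (a - j * spec.pitch) ** 2 + (b - i * spec.pitch) ** 2
    in_hole = on_board & (d2 <= (spec.diameter / 2.0) ** 2)
    img = np.full(rays.shape[:2], float(bg))
    img[on_board] = board
    img[in_hole] = hole
    return _downsample(img, supersample)


def render_calibration_scene(
    rig: RigConfig,
    spec: GridSpec,
    target_pose: Pose,
    *,
    dropout: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    supersample: int = 3,
) -> CalibrationScene:
    """Render the circle target into all three views plus the cloud.

    Circles render dark on a bright board in every modality (the thermal
    view is the black-and-white temperature coding; RGB contrast is what a
    dark backing sheet behind the holes provides). The organized cloud
    holds the true ray-board intersection per ToF pixel, NaN off the board
    or out of range, with an optional dropout fraction knocked out at
    random. Ground-truth centers are emitted row-major for each modality.
    """
    rng = np.random.default_rng(seed)
    centers_3d = target_pose.apply(spec.object_points())
    identity = Pose.identity()
    poses = {
        "tof": identity, "thermal": rig.pose_thermal, "rgb": rig.pose_rgb,
    }
    cams = {"tof": rig.tof, "thermal": rig.thermal, "rgb": rig.rgb}
    gt_centers = {}
    for mod in poses:
        uv = project_points(centers_3d, poses[mod], cams[mod],
                            apply_distortion=False)
        cam = cams[mod]
        if not np.all(
            (uv[:, 0] >= 0) & (uv[:, 0] < cam.width)
            & (uv[:, 1] >= 0) & (uv[:, 1] < cam.height)
        ):
            raise VisibilityError(f"target not fully visible in {mod} frustum")
        gt_centers[mod] = uv

    levels = {"thermal": (25, 215, 45), "rgb": (35, 205, 55), "tof": (20, 185, 40)}
    images = {}
    for mod in poses:
        img = _render_target_view(
            cams[mod], poses[mod], target_pose, spec, levels[mod], supersample
        )
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        if mod == "rgb":
            img = np.stack([img] * 3, axis=-1)
        images["tof_mono" if mod == "tof" else mod] = img

    # organized cloud: true ray-board intersection per ToF pixel
    cam_from_target = target_pose  # ToF frame == cloud frame
    R, t = cam_from_target.R, cam_from_target.tvec
    n = R[:, 2]
    rays = _pixel_rays(rig.tof, 1)
    denom = rays @ n
    s = (t @ n) / np.where(np.abs(denom) < 1e-12, np.nan, denom)
    q = rays * s[..., None]
    rel = q - t
    a = rel @ R[:, 0]
    b = rel @ R[:, 1]
    margin = spec.pitch
    valid = (
        (s > rig.tof_range[0]) & (s < rig.tof_range[1])
        & (a >= -margin) & (a <= (spec.cols - 1) * spec.pitch + margin)
        & (b >= -margin) & (b <= (spec.rows - 1) * spec.pitch + margin)
    )
    if dropout > 0:
        valid &= rng.random(valid.shape) >= dropout
    pts = np.where(valid[..., None], q, np.nan)
    cloud = OrganizedPointCloud(pts)

    return CalibrationScene(
        images=images, cloud=cloud, centers_3d=centers_3d,
        gt_centers=gt_centers, rig=rig, spec=spec, target_pose=target_pose,
    )


def calibration_correspondences(
    rig: RigConfig,
    spec: GridSpec,
    target_pose: Pose,
    modality: str = "thermal",
    *,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> CorrespondenceSet:
    """Exact 3D-2D correspondences of a calibration scene, no rendering.

    The geometry-only fast path for solver studies: true circle centers in
    the ToF frame paired with their true projections in the chosen camera,
    optionally perturbed by Gaussian pixel noise.
    """
    cam = {"thermal": rig.thermal, "rgb": rig.rgb}[modality]
    pose = {"thermal": rig.pose_thermal, "rgb": rig.pose_rgb}[modality]
    obj = target_pose.apply(spec.object_points())
    uv = project_points(obj, pose, cam, apply_distortion=True)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng()
        uv = uv + rng.normal(0.0, noise_sigma, uv.shape)
    return CorrespondenceSet(obj, uv, modality=modality)


# ------------------------------------------------------------------ phantom


PART_NONE, PART_HEAD, PART_TORSO, PART_NOSE, PART_INTERVENTION = 0, 1, 2, 3, 4

PART_COLORS = {
    PART_NONE: (20, 22, 28),
    PART_HEAD: (205, 160, 140),
    PART_TORSO: (70, 110, 190),
    PART_NOSE: (225, 140, 120),
    PART_INTERVENTION: (235, 235, 230),
}
PART_THERMAL = {
    PART_NONE: 25,
    PART_HEAD: 220,
    PART_TORSO: 140,
    PART_NOSE: 200,
    PART_INTERVENTION: 180,
}
_PART_CLASS = {
    PART_HEAD: "head",
    PART_NOSE: "nose",
    PART_TORSO: "torso",
    PART_INTERVENTION: "intervention",
}


@dataclass
class PhantomSpec:
    """Neonate-like phantom: axis-aligned ellipsoids in the phantom frame.

    The frame has +Z pointing away from the cameras, so front surfaces
    (face, chest) are at negative local Z. Sizes approximate a late
    pre-term neonate: a ~9 cm head and a ~22 cm swaddled torso.
    """

    head_center: tuple = (0.0, -0.085, 0.0)
    head_radii: tuple = (0.045, 0.05, 0.04)
    torso_center: tuple = (0.0, 0.06, 0.01)
    torso_radii: tuple = (0.075, 0.11, 0.05)
    nose_center: tuple = (0.0, -0.088, -0.040)
    nose_radius: float = 0.010
    intervention_center: tuple | None = None
    intervention_radii: tuple = (0.03, 0.05, 0.02)

    def parts(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        out = [
            (PART_HEAD, np.array(self.head_center), np.array(self.head_radii)),
            (PART_TORSO, np.array(self.torso_center), np.array(self.torso_radii)),
            (PART_NOSE, np.array(self.nose_center),
             np.array([self.nose_radius] * 3)),
        ]
        if self.intervention_center is not None:
            out.append(
                (PART_INTERVENTION, np.array(self.intervention_center),
                 np.array(self.intervention_radii))
            )
        return out


def default_phantom() -> PhantomSpec:
    return PhantomSpec()


@dataclass
class PhantomScene:
    """Rendered phantom triple with clouds, part maps and tight boxes."""

    images: dict  # 'thermal' (H,W) u8, 'rgb' (H,W,3) u8, 'tof_mono' (H,W) u8
    cloud: OrganizedPointCloud
    part_maps: dict  # modality -> (H, W) int part-id map
    boxes: dict = dc_field(default_factory=dict)  # modality -> {class: BBox}
    rig: RigConfig | None = None
    pose: Pose | None = None

    def cloud_part_ids(self) -> np.ndarray:
        """Flat per-cloud-point part id (ToF part map, row-major)."""
        return self.part_maps["tof"].ravel()


def _trace_parts(
    cam: CameraModel,
    cam_from_phantom: Pose,
    spec: PhantomSpec,
    max_range: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Ray-trace the phantom: per-pixel depth (camera Z) and part id."""
    phantom_from_cam = cam_from_phantom.inverse()
    Rp, tp = phantom_from_cam.R, phantom_from_cam.tvec
    rays = _pixel_rays(cam, 1)
    d_p = rays @ Rp.T  # ray directions in phantom frame
    depth = np.full(rays.shape[:2], np.inf)
    part = np.zeros(rays.shape[:2], dtype=np.int8)
    for pid, center, radii in spec.parts():
        o = (tp - center) / radii
        d = d_p / radii
        a = np.sum(d * d, axis=-1)
        b = np.sum(d * o, axis=-1)
        c0 = float(o @ o) - 1.0
        disc = b * b - a * c0
        hit = disc >= 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        s1 = (-b - sq) / a
        s2 = (-b + sq) / a
        s = np.where(s1 > 1e-9, s1, s2)
        ok = hit & (s > 1e-9) & (s < max_range) & (s < depth)
        depth = np.where(ok, s, depth)
        part = np.where(ok, pid, part)
    return depth, part


def _boxes_from_parts(part: np.ndarray) -> dict:
    """Tight silhouette boxes per class; the head box includes the nose."""
    out = {}
    groups = {
        "head": (PART_HEAD, PART_NOSE),
        "nose": (PART_NOSE,),
        "torso": (PART_TORSO,),
        "intervention": (PART_INTERVENTION,),
    }
    for cls, pids in groups.items():
        mask = np.isin(part, pids)
        if not mask.any():
            continue
        rows = np.nonzero(mask.any(axis=1))[0]
        cols = np.nonzero(mask.any(axis=0))[0]
        out[cls] = BBox(
            label=cls,
            x_min=float(cols[0]), y_min=float(rows[0]),
            x_max=float(cols[-1] + 1), y_max=float(rows[-1] + 1),
        )
    return out


def render_phantom_scene(
    rig: RigConfig,
    spec: PhantomSpec,
    pose: Pose,
    *,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    dropout: float = 0.0,
) -> PhantomScene:
    """Render the phantom into all three views with labels and cloud.

    ``pose`` maps the phantom frame into the ToF frame. Geometry is fully
    determined by the pose; the seed only drives optional pixel noise and
    cloud dropout, so two seeds at the same pose differ in noise alone.
    """
    rng = np.random.default_rng(seed)
    poses = {
        "tof": Pose.identity(),
        "thermal": rig.pose_thermal,
        "rgb": rig.pose_rgb,
    }
    cams = {"tof": rig.tof, "thermal": rig.thermal, "rgb": rig.rgb}
    part_maps, boxes, images = {}, {}, {}
    depth_tof = None
    for mod in poses:
        cam_from_phantom = poses[mod].compose(pose)
        depth, part = _trace_parts(cams[mod], cam_from_phantom, spec,
                                   rig.tof_range[1])
        part_maps[mod] = part
        boxes[mod] = _boxes_from_parts(part)
        if mod == "tof":
            depth_tof = depth
        if mod == "rgb":
            lut = np.zeros((5, 3))
            for pid, color in PART_COLORS.items():
                lut[pid] = color
            img = lut[part]
        else:
            lut = np.zeros(5)
            for pid, level in PART_THERMAL.items():
                lut[pid] = level
            img = lut[part]
            if mod == "tof":
                img = np.where(part > 0, 170.0, 15.0)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        images["tof_mono" if mod == "tof" else mod] = np.clip(
            np.rint(img), 0, 255
        ).astype(np.uint8)

    rays = _pixel_rays(rig.tof, 1)
    valid = (
        np.isfinite(depth_tof)
        & (depth_tof > rig.tof_range[0])
        & (depth_tof < rig.tof_range[1])
    )
    if dropout > 0:
        valid &= rng.random(valid.shape) >= dropout
    depth_safe = np.where(valid, depth_tof, 0.0)
    pts = np.where(valid[..., None], rays * depth_safe[..., None], np.nan)
    cloud = OrganizedPointCloud(pts)
    # mask the part map where the cloud is invalid so cloud_part_ids aligns
    part_maps["tof"] = np.where(valid, part_maps["tof"], PART_NONE)

    return PhantomScene(
        images=images, cloud=cloud, part_maps=part_maps, boxes=boxes,
        rig=rig, pose=pose,
    )


# ------------------------------------------------------------------- disk IO


def write_scene(out_dir, scene) -> None:
    """Write a rendered scene to disk in open formats.

    PNG images, ASCII PCD cloud, per-camera intrinsics YAML, a true-pose
    YAML, and (for phantom scenes) YOLO-txt plus COCO-JSON labels per
    modality; calibration scenes get their ground-truth centers as CSV.
    Everything round-trips through the package's own readers.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, img in scene.images.items():
        iio.imwrite(out / f"{name}.png", img)
    write_pcd(scene.cloud, out / "cloud.pcd")
    rig = scene.rig
    for cam in (rig.thermal, rig.rgb, rig.tof):
        save_intrinsics(cam, out / f"intrinsics_{cam.name}.yaml")
    poses = {
        "thermal": rig.pose_thermal,
        "rgb": rig.pose_rgb,
    }
    pose_doc = {
        mod: {"rvec": [float(x) for x in p.rvec],
              "tvec": [float(x) for x in p.tvec]}
        for mod, p in poses.items()
    }
    with open(out / "true_poses.yaml", "w") as fh:
        yaml.safe_dump(pose_doc, fh, sort_keys=False)

    if isinstance(scene, CalibrationScene):
        with open(out / "gt_centers.csv", "w") as fh:
            fh.write("index,modality,u,v\n")
            for mod, uv in scene.gt_centers.items():
                for i, (u, v) in enumerate(uv):
                    fh.write(f"{i},{mod},{u:.9g},{v:.9g}\n")
    else:
        cams = {"thermal": rig.thermal, "rgb": rig.rgb, "tof": rig.tof}
        coco_frames = {}
        for mod, cls_boxes in scene.boxes.items():
            cam = cams[mod]
            name = "tof_mono" if mod == "tof" else mod
            bxs = list(cls_boxes.values())
            write_yolo_txt(bxs, out / f"{name}.txt", cam.width, cam.height)
            coco_frames[f"{name}.png"] = (cam.width, cam.height, bxs)
        write_coco_json(coco_frames, out / "labels_coco.json")


def load_true_poses(path) -> dict:
    """Read a true-pose YAML back into ``{modality: Pose}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {
        mod: Pose(np.array(d["rvec"], float), np.array(d["tvec"], float))
        for mod, d in doc.items()
    }
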