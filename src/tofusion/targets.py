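"""Calibration-target detection and 2D-3D correspondence building.

The calibration target is a plate perforated with a regular grid of circles
(by default 6 rows x 20 columns, 1 cm diameter, 13.96 mm center pitch); the
holes appear as high-contrast blobs in all three modalities: cold disks in
the thermal image, dark disks in RGB, and depth dropouts / background hits
in the ToF mono image. Detecting the circle centers in the ToF mono image
gives, via the organized point cloud, their 3D coordinates; detecting the
same centers in a 2D camera gives their pixel projections. Pairing the two
by grid index yields the 3D-2D correspondence set a PnP solver needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .camera import round_half_away
from .errors import (
    GridIncompleteError,
    InsufficientCorrespondencesError,
    InvalidParameterError,
    NoDepthError,
    OrderingFailedError,
)
from .pointcloud import OrganizedPointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "Keypoint",
    "GridSpec",
    "CorrespondenceSet",
    "BlobDetectorConfig",
    "threshold_thermal",
    "detect_blobs",
    "order_grid",
    "lookup_tof_3d",
    "build_correspondences",
    "read_correspondences_csv",
    "write_correspondences_csv",
]

MIN_CORRESPONDENCES = 6


@dataclass(frozen=True)
class Keypoint:
    """Sub-pixel blob center with its approximate diameter in pixels."""

    u: float
    v: float
    size: float = 0.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the circle calibration target.

    Defaults follow the target used for the rig: 6 x 20 circles of 1 cm
    diameter at 13.96 mm pitch, mounted with the long edge horizontal.
    """

    rows: int = 6
    cols: int = 20
    diameter: float = 0.01
    pitch: float = 0.01396

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise InvalidParameterError("grid needs at least 2 rows and 2 columns")
        if not (self.pitch > self.diameter > 0):
            raise InvalidParameterError("require pitch > diameter > 0")

    @property
    def count(self) -> int:
        return self.rows * self.cols

    def object_points(self) -> np.ndarray:
        """Row-major circle centers in the target plane (Z=0), meters.

        Top-left circle at the origin, +X along the long (column) edge,
        +Y down the short (row) edge.
        """
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        pts = np.zeros((self.count, 3))
        pts[:, 0] = jj.ravel() * self.pitch
        pts[:, 1] = ii.ravel() * self.pitch
        return pts


@dataclass
class CorrespondenceSet:
    """Paired 3D ToF points and 2D pixel coordinates for one target camera."""

    object_points: np.ndarray  # (n, 3), ToF frame, meters
    image_points: np.ndarray  # (n, 2), target camera pixels
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.object_points = np.atleast_2d(np.asarray(self.object_points, float))
        self.image_points = np.atleast_2d(np.asarray(self.image_points, float))
        if self.object_points.shape[0] != self.image_points.shape[0]:
            raise InvalidParameterError("3D and 2D lists must have equal length")
        uv = self.image_points
        if uv.shape[0] != np.unique(uv, axis=0).shape[0]:
            raise InvalidParameterError("duplicate 2D points in correspondence set")

    def __len__(self) -> int:
        return self.object_points.shape[0]


@dataclass(frozen=True)
class BlobDetectorConfig:
    """Tunable blob-detector parameters.

    ``polarity`` selects whether circles are darker or brighter than the
    background; ``circularity`` is the isoperimetric ratio 4*pi*A/P^2 below
    which a component is rejected.
    """

    min_area: float = 4.0
    max_area: float = 5000.0
    circularity: float = 0.7
    polarity: str = "dark"  # "dark" | "bright"
    threshold: float | None = None  # None -> Otsu


def threshold_thermal(img: np.ndarray, t: float) -> np.ndarray:
    """Binarize a thermal frame at temperature/intensity threshold ``t``.

    Pixels at or above ``t`` become 255, others 0. Monotone in ``t``:
    raising the threshold never turns a black pixel white.
    """
    img = np.asarray(img)
    return np.where(img >= t, 255, 0).astype(np.uint8)


def _otsu(img: np.ndarray) -> float:
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(img))


def detect_blobs(
    img: np.ndarray, config: BlobDetectorConfig | None = None
) -> list[Keypoint]:
    """Detect circular blobs in a single-channel image.

    Connected components of the binarized image are filtered by area and
    circularity; surviving components yield one keypoint each, located at
    the contrast-weighted intensity centroid for sub-pixel accuracy.
    """
    cfg = config or BlobDetectorConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("detect_blobs expects a single-channel image")
    thr = cfg.threshold if cfg.threshold is not None else _otsu(img)
    if cfg.polarity == "dark":
        fg = img < thr
        weight_img = thr - img
    elif cfg.polarity == "bright":
        fg = img > thr
        weight_img = img - thr
    else:
        raise InvalidParameterError("polarity must be 'dark' or 'bright'")
    labels = measure.label(fg, connectivity=2)
    keypoints: list[Keypoint] = []
    for region in measure.regionprops(labels):
        if not (cfg.min_area <= region.area <= cfg.max_area):
            continue
        perim = region.perimeter_crofton if region.perimeter > 0 else 0.0
        if perim > 0:
            circ = 4.0 * np.pi * region.area / (perim**2)
            if circ < cfg.circularity:
                continue
        rows, cols = region.coords[:, 0], region.coords[:, 1]
        w = np.clip(weight_img[rows, cols], 0.0, None)
        if w.sum() <= 0:
            w = np.ones_like(w)
        u = float(np.average(cols, weights=w))
        v = float(np.average(rows, weights=w))
        size = float(2.0 * np.sqrt(region.area / np.pi))
        keypoints.append(Keypoint(u=u, v=v, size=size))
    return keypoints


def order_grid(kps: list[Keypoint] | np.ndarray, spec: GridSpec) -> np.ndarray:
    """Order detected grid centers row-major, top-left first.

    The point set is de-rotated by its principal axis (the long, horizontal
    edge of the target), rows are formed by clustering the transverse
    coordinate, and points are sorted within each row. The result is a pure
    function of the point set: shuffling the input leaves the output order
    unchanged.

    Returns an ``(rows*cols, 2)`` array of ``(u, v)`` centers.
    """
    if isinstance(kps, np.ndarray):
        pts = np.atleast_2d(np.asarray(kps, dtype=float))[:, :2].copy()
    else:
        pts = np.array([[k.u, k.v] for k in kps], dtype=float)
    if pts.shape[0] != spec.count:
        raise GridIncompleteError(
            f"expected {spec.count} keypoints, got {pts.shape[0]}"
        )
    centered = pts - pts.mean(axis=0)
    # principal axis of the point set = direction of the long grid edge
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:  # long edge points rightward (+u)
        axis = -axis
    ortho = np.array([-axis[1], axis[0]])
    if ortho[1] < 0:  # transverse axis points downward (+v)
        ortho = -ortho
    along = centered @ axis
    across = centered @ ortho

    order = np.argsort(across, kind="stable")
    sorted_across = across[order]
    gaps = np.diff(sorted_across)
    # rows are separated by the (rows-1) largest gaps in the transverse coord
    n_cuts = spec.rows - 1
    cut_idx = np.sort(np.argsort(gaps)[::-1][:n_cuts])
    row_bounds = np.split(order, cut_idx + 1)
    if len(row_bounds) != spec.rows or any(
        len(r) != spec.cols for r in row_bounds
    ):
        raise OrderingFailedError(
            "transverse clustering did not yield "
            f"{spec.rows} rows of {spec.cols} points"
        )
    # sanity: inter-row gaps must dominate intra-row scatter
    intra = max(
        (sorted_across_r.max() - sorted_across_r.min())
        for sorted_across_r in (across[r] for r in row_bounds)
    )
    inter = min(gaps[i] for i in cut_idx)
    if intra > 0 and inter < 1.5 * intra:
        raise OrderingFailedError("ambiguous row clustering")

    ordered = []
    for row in row_bounds:
        row_sorted = row[np.argsort(along[row], kind="stable")]
        ordered.extend(row_sorted.tolist())
    return pts[np.array(ordered)]


def lookup_tof_3d(px, cloud: OrganizedPointCloud) -> np.ndarray:
    """3D point of an integer ToF mono-image pixel via the organized cloud."""
    u, v = int(px[0]), int(px[1])
    return cloud.lookup(u, v)


def build_correspondences(
    ordered_tof_centers: np.ndarray,
    ordered_cam_centers: np.ndarray,
    cloud: OrganizedPointCloud,
    *,
    modality: str = "unknown",
) -> CorrespondenceSet:
    """Pair grid-ordered ToF centers (via cloud lookup) with camera centers.

    Sub-pixel ToF centers are rounded to the nearest mono pixel before the
    cloud lookup. Pairs whose 3D lookup fails (dropout or out of bounds)
    are dropped with a logged count; fewer than 6 survivors is an error.
    """
    tof = np.atleast_2d(np.asarray(ordered_tof_centers, dtype=float))
    cam = np.atleast_2d(np.asarray(ordered_cam_centers, dtype=float))
    if tof.shape[0] != cam.shape[0]:
        raise InvalidParameterError("center lists must have equal length")
    obj, img = [], []
    dropped = 0
    for (tu, tv), uv in zip(tof, cam):
        u, v = int(round_half_away(tu)), int(round_half_away(tv))
        try:
            p = cloud.lookup(u, v)
        except (IndexError, NoDepthError):
            dropped += 1
            continue
        obj.append(p)
        img.append(uv)
    if dropped:
        logger.info("dropped %d/%d correspondences without valid depth",
                    dropped, tof.shape[0])
    if len(obj) < MIN_CORRESPONDENCES:
        raise InsufficientCorrespondencesError(
            f"only {len(obj)} usable correspondences (need >= {MIN_CORRESPONDENCES})"
        )
    return CorrespondenceSet(np.array(obj), np.array(img), modality=modality)


def write_correspondences_csv(corr: CorrespondenceSet, path) -> None:
    """Write a correspondence set as CSV with columns X,Y,Z,u,v,modality."""
    with open(path, "w") as fh:
        fh.write("X,Y,Z,u,v,modality\n")
        for (X, Y, Z), (u, v) in zip(corr.object_points, corr.image_points):
            fh.write(f"{X:.9g},{Y:.9g},{Z:.9g},{u:.9g},{v:.9g},{corr.modality}\n")


def read_correspondences_csv(path) -> CorrespondenceSet:
    """Read a correspondence CSV (columns X,Y,Z,u,v,modality).

    Supports the manual per-subject refinement workflow: significant scene
    points picked by hand can be supplied as extra correspondences.
    """
    import csv

    obj, img, modality = [], [], "unknown"
    with open(path) as fh:
        for row in csv.DictReader(fh):
            obj.append([float(row["X"]), float(row["Y"]), float(row["Z"])])
            img.append([float(row["u"]), float(row["v"])])
            modality = row.get("modality", modality) or modality
    return CorrespondenceSet(np.array(obj), np.array(img), modality=modality)
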