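"""Bounding-box-aware data augmentation for detection corpora.

Eleven classical operators, each of which transforms the image and its
annotations together so that no relabeling is ever needed:

geometric (boxes remapped)
    mirror (x / y / both axes), rotation in 90-degree increments with a
    resize back to the original frame size, center zoom with factor
    U(0.5, 1.5), random crop (content moved to the top-left of a black
    canvas; boxes kept only if at least 75% of their area stays visible),
    random erasing of up to three rectangles (boxes discarded when more
    than 50% of their area is erased);

photometric (boxes untouched)
    salt-and-pepper or Gaussian noise, contrast scaling by U(0.5, 0.75),
    saturation/brightness shift by U(0.1, 0.5) in HSV space, Gaussian blur
    with sigma U(2, 4), sharpening with a random unit-sum 3x3 kernel, and
    histogram equalization of the luma channel in YCbCr space.

All randomness flows through a numpy Generator; dataset-level application
is reproducible bit-for-bit from a single global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .annotations import BBox
from .errors import InvalidParameterError

__all__ = [
    "AnnotatedFrame",
    "AugmentationPlan",
    "mirror",
    "rotate90_resize",
    "zoom_center",
    "random_crop",
    "random_erase",
    "add_noise",
    "adjust_contrast",
    "adjust_saturation_brightness",
    "blur_or_sharpen",
    "equalize_histogram",
    "augment_dataset",
    "apply_operator",
    "OPERATOR_NAMES",
]


@dataclass
class AnnotatedFrame:
    """One image of any modality plus its class-labeled boxes."""

    image: np.ndarray
    boxes: list[BBox] = field(default_factory=list)
    modality: str = "thermal"
    seed: int | None = None

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]


def _clip_boxes(boxes: list[BBox], width: float, height: float) -> list[BBox]:
    out = []
    for b in boxes:
        c = b.clipped(width, height)
        if c is not None:
            out.append(c)
    return out


def _cast_like(arr: np.ndarray, ref: np.ndarray) -> np.ndarray:
    if np.issubdtype(ref.dtype, np.integer):
        info = np.iinfo(ref.dtype)
        return np.clip(np.rint(arr), info.min, info.max).astype(ref.dtype)
    return arr.astype(ref.dtype)


# ---------------------------------------------------------------- geometric


def mirror(f: AnnotatedFrame, axis: str = "x") -> AnnotatedFrame:
    """Mirror the frame about the x-axis, y-axis or both.

    ``axis='x'`` flips horizontally (u -> W - u), ``'y'`` vertically,
    ``'both'`` does both. An involution: mirroring twice on the same axis
    restores the frame bit-for-bit.
    """
    if axis not in ("x", "y", "both"):
        raise InvalidParameterError("axis must be 'x', 'y' or 'both'")
    img = f.image
    W, H = f.width, f.height
    boxes = f.boxes
    if axis in ("x", "both"):
        img = np.flip(img, axis=1)
        boxes = [
            replace(b, x_min=W - b.x_max, x_max=W - b.x_min) for b in boxes
        ]
    if axis in ("y", "both"):
        img = np.flip(img, axis=0)
        boxes = [
            replace(b, y_min=H - b.y_max, y_max=H - b.y_min) for b in boxes
        ]
    return replace(f, image=np.ascontiguousarray(img), boxes=boxes)


def _map_corners_rot90(corners: np.ndarray, k: int, W: int, H: int) -> np.ndarray:
    """Map (n,2) continuous points through k CCW quarter-turns + resize back."""
    pts = corners.astype(float).copy()
    w, h = float(W), float(H)
    for _ in range(k % 4):
        u, v = pts[:, 0].copy(), pts[:, 1].copy()
        pts[:, 0] = v
        pts[:, 1] = w - u
        w, h = h, w
    pts[:, 0] *= W / w
    pts[:, 1] *= H / h
    return pts


def rotate90_resize(f: AnnotatedFrame, k: int) -> AnnotatedFrame:
    """Rotate by ``k`` counter-clockwise quarter-turns, then resize back.

    Only 90-degree increments are supported (arbitrary angles would require
    relabeling). Odd ``k`` swaps the aspect ratio, so the rotated image is
    resized back to the original frame size; ``k=2`` needs no resize and is
    pixel-exact. Boxes are rotated and rescaled by the same mapping.
    """
    if k % 4 not in (1, 2, 3):
        raise InvalidParameterError("k must be 1, 2 or 3 quarter-turns")
    k = k % 4
    W, H = f.width, f.height
    img = np.rot90(f.image, k)
    if img.shape[:2] != f.image.shape[:2]:
        from skimage.transform import resize

        out = resize(
            img.astype(float), (H, W) + img.shape[2:], order=1,
            anti_aliasing=True, preserve_range=True,
        )
        img = _cast_like(out, f.image)
    else:
        img = np.ascontiguousarray(img)
    boxes = []
    for b in f.boxes:
        corners = np.array(
            [[b.x_min, b.y_min], [b.x_max, b.y_min],
             [b.x_min, b.y_max], [b.x_max, b.y_max]]
        )
        m = _map_corners_rot90(corners, k, W, H)
        boxes.append(
            replace(
                b,
                x_min=float(m[:, 0].min()), y_min=float(m[:, 1].min()),
                x_max=float(m[:, 0].max()), y_max=float(m[:, 1].max()),
            )
        )
    return replace(f, image=img, boxes=_clip_boxes(boxes, W, H))


def zoom_center(
    f: AnnotatedFrame,
    factor: float | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotatedFrame:
    """Zoom in or out about the image center, canvas size unchanged.

    The factor defaults to U(0.5, 1.5). Zooming out pads black; zooming in
    crops. Boxes are scaled about the center and clipped; boxes pushed
    fully outside are dropped.
    """
    if factor is None:
        rng = rng or np.random.default_rng()
        factor = float(rng.uniform(0.5, 1.5))
    if factor <= 0:
        raise InvalidParameterError("zoom factor must be positive")
    W, H = f.width, f.height
    if factor == 1.0:
        return replace(f, image=f.image.copy(), boxes=list(f.boxes))
    # inverse map: source = center + (dest - center)/factor
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    matrix = np.eye(2) / factor
    offset = np.array([cy - cy / factor, cx - cx / factor])

    def warp(ch: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            ch.astype(float), matrix, offset=offset, order=1,
            mode="constant", cval=0.0,
        )

    if f.image.ndim == 2:
        out = warp(f.image)
    else:
        out = np.stack(
            [warp(f.image[..., c]) for c in range(f.image.shape[2])], axis=-1
        )
    img = _cast_like(out, f.image)
    bcx, bcy = W / 2.0, H / 2.0
    boxes = [
        replace(
            b,
            x_min=bcx + (b.x_min - bcx) * factor,
            y_min=bcy + (b.y_min - bcy) * factor,
            x_max=bcx + (b.x_max - bcx) * factor,
            y_max=bcy + (b.y_max - bcy) * factor,
        )
        for b in f.boxes
    ]
    return replace(f, image=img, boxes=_clip_boxes(boxes, W, H))


def random_crop(
    f: AnnotatedFrame,
    rng: np.random.Generator | None = None,
    rect: tuple[int, int, int, int] | None = None,
    min_visible: float = 0.75,
) -> AnnotatedFrame:
    """Crop a random sub-rectangle and place it at the top-left of a black
    canvas of the original size.

    Each box is intersected with the crop window; boxes keeping at least
    ``min_visible`` (default 75%) of their area are shifted into the new
    frame, the rest are discarded. ``rect=(x0, y0, w, h)`` overrides the
    random window for deterministic use.
    """
    W, H = f.width, f.height
    if rect is None:
        rng = rng or np.random.default_rng()
        x0 = int(rng.integers(0, W // 2 + 1))
        y0 = int(rng.integers(0, H // 2 + 1))
        w = int(rng.integers(max(W // 4, 1), W - x0 + 1))
        h = int(rng.integers(max(H // 4, 1), H - y0 + 1))
    else:
        x0, y0, w, h = rect
    if not (0 <= x0 < W and 0 <= y0 < H and w > 0 and h > 0
            and x0 + w <= W and y0 + h <= H):
        raise InvalidParameterError("crop rectangle outside the frame")
    canvas = np.zeros_like(f.image)
    canvas[:h, :w] = f.image[y0 : y0 + h, x0 : x0 + w]
    boxes = []
    for b in f.boxes:
        ix0, iy0 = max(b.x_min, x0), max(b.y_min, y0)
        ix1, iy1 = min(b.x_max, x0 + w), min(b.y_max, y0 + h)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        visible = (ix1 - ix0) * (iy1 - iy0) / b.area
        if visible < min_visible:
            continue
        boxes.append(
            replace(b, x_min=ix0 - x0, y_min=iy0 - y0,
                    x_max=ix1 - x0, y_max=iy1 - y0)
        )
    return replace(f, image=canvas, boxes=boxes)


def _union_area_in_box(rects, b: BBox) -> float:
    """Exact area of (union of up to 3 rects) ∩ box, by inclusion-exclusion."""

    def inter(r1, r2):
        if r1 is None or r2 is None:
            return None
        x0, y0 = max(r1[0], r2[0]), max(r1[1], r2[1])
        x1, y1 = min(r1[2], r2[2]), min(r1[3], r2[3])
        if x0 >= x1 or y0 >= y1:
            return None
        return (x0, y0, x1, y1)

    def area(r):
        return 0.0 if r is None else (r[2] - r[0]) * (r[3] - r[1])

    bb = (b.x_min, b.y_min, b.x_max, b.y_max)
    clipped = [r for r in (inter(r, bb) for r in rects) if r is not None]
    total = sum(area(r) for r in clipped)
    for i in range(len(clipped)):
        for j in range(i + 1, len(clipped)):
            total -= area(inter(clipped[i], clipped[j]))
    if len(clipped) == 3:
        total += area(inter(inter(clipped[0], clipped[1]), clipped[2]))
    return total


def random_erase(
    f: AnnotatedFrame,
    rng: np.random.Generator | None = None,
    rects: list[tuple[float, float, float, float]] | None = None,
    max_overlap: float = 0.5,
) -> AnnotatedFrame:
    """Black out 1-3 random rectangles.

    A box is discarded when the erased fraction of its area exceeds
    ``max_overlap`` (strictly more than 50% by default); exactly 50% is
    kept. ``rects`` as ``(x0, y0, x1, y1)`` tuples overrides sampling.
    """
    W, H = f.width, f.height
    if rects is None:
        rng = rng or np.random.default_rng()
        n = int(rng.integers(1, 4))
        rects = []
        for _ in range(n):
            w = int(rng.integers(max(W // 20, 1), max(W // 4, 2)))
            h = int(rng.integers(max(H // 20, 1), max(H // 4, 2)))
            x0 = int(rng.integers(0, max(W - w, 1)))
            y0 = int(rng.integers(0, max(H - h, 1)))
            rects.append((x0, y0, x0 + w, y0 + h))
    img = f.image.copy()
    for x0, y0, x1, y1 in rects:
        ix0, iy0 = max(int(np.floor(x0)), 0), max(int(np.floor(y0)), 0)
        ix1, iy1 = min(int(np.ceil(x1)), W), min(int(np.ceil(y1)), H)
        if ix0 < ix1 and iy0 < iy1:
            img[iy0:iy1, ix0:ix1] = 0
    boxes = []
    for b in f.boxes:
        erased = _union_area_in_box(rects, b)
        if erased / b.area > max_overlap:
            continue
        boxes.append(b)
    return replace(f, image=img, boxes=boxes)


# --------------------------------------------------------------- photometric


def _value_range(img: np.ndarray) -> tuple[float, float]:
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0


def add_noise(
    f: AnnotatedFrame,
    kind: str = "salt_pepper",
    rng: np.random.Generator | None = None,
    *,
    fraction: float = 0.02,
    sigma: float = 10.0,
) -> AnnotatedFrame:
    """Add salt-and-pepper (impulse) or Gaussian noise; boxes unchanged.

    Salt-and-pepper flips each pixel independently with probability
    ``fraction`` to the minimum or maximum of the value range; Gaussian
    adds zero-mean noise of standard deviation ``sigma`` (image units),
    clipped to range.
    """
    rng = rng or np.random.default_rng()
    lo, hi = _value_range(f.image)
    img = f.image.copy()
    if kind == "salt_pepper":
        if not (0.0 <= fraction <= 1.0):
            raise InvalidParameterError("fraction must lie in [0, 1]")
        hit = rng.random(img.shape[:2]) < fraction
        salt = rng.random(img.shape[:2]) < 0.5
        img[hit & salt] = hi
        img[hit & ~salt] = lo
    elif kind == "gaussian":
        noise = rng.normal(0.0, sigma, size=img.shape)
        img = _cast_like(np.clip(img.astype(float) + noise, lo, hi), f.image)
    else:
        raise InvalidParameterError("kind must be 'salt_pepper' or 'gaussian'")
    return replace(f, image=img, boxes=list(f.boxes))


def adjust_contrast(
    f: AnnotatedFrame,
    c: float | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotatedFrame:
    """Scale all pixel values by a constant c ~ U(0.5, 0.75); boxes unchanged."""
    if c is None:
        rng = rng or np.random.default_rng()
        c = float(rng.uniform(0.5, 0.75))
    if c < 0:
        raise InvalidParameterError("contrast factor must be non-negative")
    lo, hi = _value_range(f.image)
    img = _cast_like(np.clip(f.image.astype(float) * c, lo, hi), f.image)
    return replace(f, image=img, boxes=list(f.boxes))


def adjust_saturation_brightness(
    f: AnnotatedFrame,
    d: float | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotatedFrame:
    """Add d ~ U(0.1, 0.5) to saturation and value in HSV space.

    Three-channel frames are converted RGB -> HSV (channels in [0, 1]),
    ``d`` is added to S and V with clipping, and the image is converted
    back. Single-channel frames have no hue/saturation, so ``d`` acts on
    the (normalized) intensity alone. Boxes are unchanged.
    """
    from skimage.color import hsv2rgb, rgb2hsv

    if d is None:
        rng = rng or np.random.default_rng()
        d = float(rng.uniform(0.1, 0.5))
    lo, hi = _value_range(f.image)
    if f.image.ndim == 2:
        img = _cast_like(
            np.clip(f.image.astype(float) + d * (hi - lo), lo, hi), f.image
        )
    else:
        norm = (f.image.astype(float) - lo) / (hi - lo)
        hsv = rgb2hsv(norm)
        hsv[..., 1] = np.clip(hsv[..., 1] + d, 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] + d, 0.0, 1.0)
        out = hsv2rgb(hsv) * (hi - lo) + lo
        img = _cast_like(out, f.image)
    return replace(f, image=img, boxes=list(f.boxes))


def random_sharpen_kernel(rng: np.random.Generator) -> np.ndarray:
    """Random 3x3 kernel: neighbors U(-1, 1), center fixed so the sum is 1."""
    k = rng.uniform(-1.0, 1.0, size=(3, 3))
    k[1, 1] = 0.0
    k[1, 1] = 1.0 - k.sum()
    return k


def blur_or_sharpen(
    f: AnnotatedFrame,
    mode: str = "blur",
    rng: np.random.Generator | None = None,
    *,
    sigma: float | None = None,
    kernel: np.ndarray | None = None,
) -> AnnotatedFrame:
    """Gaussian blur (sigma U(2, 4), unit-sum kernel) or random 3x3 sharpen.

    Both kernels sum to one, so constant images pass through unchanged.
    Boxes are unchanged.
    """
    rng = rng or np.random.default_rng()
    lo, hi = _value_range(f.image)
    img_f = f.image.astype(float)
    if mode == "blur":
        if sigma is None:
            sigma = float(rng.uniform(2.0, 4.0))
        if f.image.ndim == 2:
            out = ndimage.gaussian_filter(img_f, sigma, mode="reflect")
        else:
            out = np.stack(
                [
                    ndimage.gaussian_filter(img_f[..., c], sigma, mode="reflect")
                    for c in range(img_f.shape[2])
                ],
                axis=-1,
            )
    elif mode == "sharpen":
        if kernel is None:
            kernel = random_sharpen_kernel(rng)
        kernel = np.asarray(kernel, dtype=float)
        if kernel.shape != (3, 3):
            raise InvalidParameterError("sharpen kernel must be 3x3")
        if f.image.ndim == 2:
            out = ndimage.convolve(img_f, kernel, mode="reflect")
        else:
            out = np.stack(
                [
                    ndimage.convolve(img_f[..., c], kernel, mode="reflect")
                    for c in range(img_f.shape[2])
                ],
                axis=-1,
            )
    else:
        raise InvalidParameterError("mode must be 'blur' or 'sharpen'")
    img = _cast_like(np.clip(out, lo, hi), f.image)
    return replace(f, image=img, boxes=list(f.boxes))


def _equalize_levels(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Histogram-equalize integer levels onto [lo, hi] via the CDF map."""
    v = np.clip(np.rint(values), lo, hi).astype(int)
    hist = np.bincount(v.ravel() - lo, minlength=hi - lo + 1)
    cdf = np.cumsum(hist)
    nz = np.nonzero(hist)[0]
    cdf_min = cdf[nz[0]] if nz.size else 0
    total = v.size
    denom = max(total - cdf_min, 1)
    lut = lo + np.rint((cdf - cdf_min) / denom * (hi - lo)).astype(int)
    return lut[v - lo]


def equalize_histogram(f: AnnotatedFrame) -> AnnotatedFrame:
    """Equalize the intensity distribution; boxes unchanged.

    Color frames are converted to YCbCr, only the luma channel is
    equalized (chroma is untouched), and the result is converted back.
    Single-channel frames are equalized directly.
    """
    from skimage.color import rgb2ycbcr, ycbcr2rgb

    lo, hi = _value_range(f.image)
    if f.image.ndim == 2:
        if np.issubdtype(f.image.dtype, np.integer):
            eq = _equalize_levels(f.image, int(lo), int(hi))
            img = eq.astype(f.image.dtype)
        else:
            levels = np.rint(f.image * 255.0)
            img = (_equalize_levels(levels, 0, 255) / 255.0).astype(f.image.dtype)
    else:
        norm = (f.image.astype(float) - lo) / (hi - lo)
        ycc = rgb2ycbcr(norm)  # Y in [16, 235]
        ycc[..., 0] = _equalize_levels(ycc[..., 0], 16, 235)
        out = ycbcr2rgb(ycc) * (hi - lo) + lo
        img = _cast_like(np.clip(out, lo, hi), f.image)
    return replace(f, image=img, boxes=list(f.boxes))


# ------------------------------------------------------------ dataset level


OPERATOR_NAMES = (
    "mirror",
    "rotate90",
    "zoom",
    "crop",
    "erase",
    "noise",
    "contrast",
    "saturation_brightness",
    "blur",
    "sharpen",
    "equalize",
)


def apply_operator(
    name: str, f: AnnotatedFrame, rng: np.random.Generator
) -> tuple[AnnotatedFrame, dict]:
    """Apply one named operator with parameters sampled from ``rng``.

    Returns the augmented frame and the sampled parameters, so a plan can
    record exactly what was done.
    """
    if name == "mirror":
        axis = ("x", "y", "both")[int(rng.integers(0, 3))]
        return mirror(f, axis), {"axis": axis}
    if name == "rotate90":
        k = int(rng.integers(1, 4))
        return rotate90_resize(f, k), {"k": k}
    if name == "zoom":
        factor = float(rng.uniform(0.5, 1.5))
        return zoom_center(f, factor), {"factor": factor}
    if name == "crop":
        out = random_crop(f, rng)
        return out, {}
    if name == "erase":
        out = random_erase(f, rng)
        return out, {}
    if name == "noise":
        kind = ("salt_pepper", "gaussian")[int(rng.integers(0, 2))]
        return add_noise(f, kind, rng), {"kind": kind}
    if name == "contrast":
        c = float(rng.uniform(0.5, 0.75))
        return adjust_contrast(f, c), {"c": c}
    if name == "saturation_brightness":
        d = float(rng.uniform(0.1, 0.5))
        return adjust_saturation_brightness(f, d), {"d": d}
    if name == "blur":
        sigma = float(rng.uniform(2.0, 4.0))
        return blur_or_sharpen(f, "blur", sigma=sigma), {"sigma": sigma}
    if name == "sharpen":
        kernel = random_sharpen_kernel(rng)
        return blur_or_sharpen(f, "sharpen", kernel=kernel), {
            "kernel": kernel.tolist()
        }
    if name == "equalize":
        return equalize_histogram(f), {}
    raise InvalidParameterError(f"unknown operator '{name}'")


@dataclass
class AugmentationPlan:
    """Dataset-level augmentation recipe.

    ``ops`` lists the operators applied per input frame, one augmented
    output per entry; the entry ``"random"`` samples an operator uniformly.
    The paper-style 1:1 corpus (1400 labeled + 1400 augmented) corresponds
    to a single-entry plan. Everything derives from ``seed``.
    """

    ops: tuple[str, ...] = ("random",)
    seed: int = 0

    def __post_init__(self) -> None:
        self.ops = tuple(self.ops)
        for op in self.ops:
            if op != "random" and op not in OPERATOR_NAMES:
                raise InvalidParameterError(f"unknown operator '{op}'")


def augment_dataset(
    frames: list[AnnotatedFrame], plan: AugmentationPlan
) -> tuple[list[AnnotatedFrame], list[dict]]:
    """Apply a plan to a corpus: one output per frame per plan entry.

    Fully reproducible: the RNG of each (frame, entry) pair is derived from
    the plan's global seed, so re-running with the same seed yields a
    byte-identical corpus.
    """
    out_frames: list[AnnotatedFrame] = []
    records: list[dict] = []
    for i, frame in enumerate(frames):
        for j, op in enumerate(plan.ops):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=plan.seed, spawn_key=(i, j))
            )
            name = op
            if name == "random":
                name = OPERATOR_NAMES[int(rng.integers(0, len(OPERATOR_NAMES)))]
            aug, params = apply_operator(name, frame, rng)
            aug.seed = plan.seed
            out_frames.append(aug)
            records.append(
                {"frame_index": i, "operator": name, "params": params}
            )
    return out_frames, records
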