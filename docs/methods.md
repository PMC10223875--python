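# Methods

## Geometric model

Every camera is an ideal pinhole with Brown–Conrady lens distortion. A
point `X` in the ToF frame maps into camera `c` via the rigid pose
`(R_c, t_c)` (stored as a Rodrigues vector plus translation in meters):
`X_c = R_c X + t_c`, normalized coordinates `(x, y) = (X_c/Z_c, Y_c/Z_c)`,
distortion

    x_d = x(1 + k1 r² + k2 r⁴ + k3 r⁶) + 2p1·x·y + p2(r² + 2x²)
    y_d = y(1 + k1 r² + k2 r⁴ + k3 r⁶) + p1(r² + 2y²) + 2p2·x·y

with `r² = x² + y²`, and pixels `u = fx·x_d + u0`, `v = fy·y_d + v0`.
The tangential terms are the standard Brown–Conrady ones, the model used
by the common calibration toolchains whose output the intrinsics YAML
carries; `r` is the radial distance of the *normalized* coordinates.
Pixels are 0-based, origin top-left, sub-pixel everywhere except final
raster writes, which round half away from zero. Image rectification is
an inverse warp (distort the output pixel's normalized position, sample
the input bilinearly, fill out-of-source samples black), so a zero
coefficient vector reproduces the input exactly.

The ToF phase-distance relation `d = φ/(2π)·λ/2` (factor ½ because the
modulated signal travels the distance twice) is implemented as stated;
the pipeline otherwise consumes the organized cloud the sensor SDK
already provides.

## Extrinsic calibration

Correspondences come from a planar circle-grid target (default 6×20
circles, 1 cm diameter, 13.96 mm pitch, long edge horizontal): blob
centers in the ToF mono image are rounded to the nearest mono pixel and
looked up in the organized cloud (no depth interpolation — the cloud is
indexed directly), giving 3D points; blob centers in the target camera
give the 2D side. Grid ordering is a pure function of the point set:
de-rotate by the principal axis, cluster the transverse coordinate into
rows at the largest gaps, sort within rows; ambiguous clustering (inter-
row gap < 1.5× intra-row scatter) is an error rather than a guess.

The PnP solve undistorts the 2D points first (keeping the linear stage
linear), initializes from the Direct Linear Transform, and refines all
six pose parameters by Levenberg–Marquardt on the full distorted-model
reprojection residuals. Because a calibration board is planar, the
12-parameter projective DLT is rank-deficient for exactly the input this
pipeline sees most; coplanarity is detected from the singular-value ratio
of the centered 3D points (threshold 1e-4) and a plane-to-image
homography decomposition (Zhang-style, with SVD re-orthonormalization
and the positive-depth sign choice) is used instead. Genuinely
rank-deficient non-planar systems still raise a degenerate-configuration
error. The solver is deterministic — no RANSAC; an optional one-shot
outlier rejection (drop residuals > 3× median, re-solve once) suits
hand-curated correspondence sets, which in practice can be as small as
~15–26 pairs; anything ≥ 6 is accepted. Reprojection quality is the
root-mean-square of Euclidean pixel residuals.

## Fusion and label transfer

The fusion image lives on the thermal pixel grid (640×480): the canvas
is the thermal frame expanded to 3 channels, and for every finite cloud
point whose projections land inside both frames the nearest-pixel RGB
sample is written at the nearest thermal pixel. Nearest-pixel sampling
(not bilinear) keeps per-pixel provenance exact; a provenance mask and a
contributing-point index map record which cloud point colored each
pixel. When two points collide on one thermal pixel the smaller thermal-
frame depth wins — crude occlusion handling that is correct for the
convex phantom and conservative otherwise. No hole filling is done by
default (a 224×171 cloud colors at most ~6% of a 640×480 frame); an
optional 3×3 dilation is available behind a flag and marked separately
in the provenance mask. The thermal base canvas is whatever thermal
rendering is supplied — raw-intensity grayscale or false-color — since
the geometry is independent of the thermal value coding.

Box transfer projects all finite cloud points into the source camera,
keeps those inside the box, projects them into the destination camera
and takes the clipped axis-aligned envelope. The necessary condition —
the ROI must be supported by the cloud — is enforced: zero supporting
points raises `RoiOutsideCloudError`. The envelope is slightly inside
the true silhouette box (the cloud samples surface points, not
silhouette edges), which is why the transfer-IoU acceptance threshold is
0.9 rather than ~1. The data-efficiency figure is
`floor(100·(n_modalities − n_manual)/n_modalities)`, the integer 66 for
(3, 1).

## Augmentation

The eleven operators and their parameter ranges: mirror about x/y/both;
rotation restricted to 90° increments with a resize back to the original
frame size (640×480 thermal/fusion, 1146×716 RGB); center zoom with
factor U(0.5, 1.5); random crop moved to the top-left of a black canvas,
boxes kept iff ≥ 75% of their area stays visible; random erase of 1–3
rectangles, boxes discarded iff strictly more than 50% of their area is
erased (the boundary semantics follow the "less than 75%" / "more than
50%" phrasing literally); salt-and-pepper noise (default corrupted
fraction 0.02) or Gaussian noise (default σ = 10 of 255 levels) — both
magnitudes are this package's defaults, exposed as parameters; contrast
scaling U(0.5, 0.75); saturation/brightness shift U(0.1, 0.5) added to S
and V in HSV; Gaussian blur σ U(2, 4) (unit-mass kernel); sharpening by
a random 3×3 kernel with neighbor weights U(−1, 1) and the center set so
the kernel sums to 1 (identity on constants — "random weights" alone
would be unbounded); histogram equalization of the luma channel in YCbCr
with chroma untouched (gamut clipping on conversion back to RGB can
still bend chroma at saturated pixels; this is inherent to the
operator). Erase-overlap areas are computed exactly by
inclusion–exclusion over ≤ 3 rectangles, matching a rasterized-mask
count.

A quarter-turn of a non-square frame must be resampled back to the
original size, so only the 180° rotation is a pixel-bit-exact
involution; the *box* mapping of four composed quarter-turns is the
identity to < 1 px, and that is the invariant tested. Dataset-level
application derives one RNG per (frame, plan-entry) pair from a single
global seed via seed sequences, so reruns are byte-identical; one plan
entry per frame reproduces the 1:1 labeled:augmented corpus ratio.

## Evaluation

Greedy confidence-ordered matching at IoU ≥ 0.5 (stable sort, so equal
confidences keep input order), each ground truth claimable once, no
cross-class matching. AP defaults to all-point interpolation (area under
the precision envelope); the 11-point variant is switchable since
detector repos differ and neither convention is canonical here.
Best-epoch selection maximizes mean AP over the classes of interest with
earliest-epoch tie-breaking.

## Synthetic rig

The generator renders registered thermal/RGB/ToF views by analytic
ray–plane (target board) and ray–ellipsoid (phantom) intersection with a
z-buffer; images are supersampled 3× for anti-aliasing, but every
geometric ground truth (2D centers, clouds, silhouette boxes) is exact.
Resolutions and fields of view mirror the physical rig: thermal 640×480
at 90°×64°, ToF 224×171 at 62°×45° with a 0.1–4 m range; focal lengths
derive from the FoV via `fx = (W/2)/tan(FoV_h/2)` (derived quantities,
not manufacturer values). The physical RGB camera is a 185° fisheye,
which a pinhole cannot represent; the synthetic RGB camera is a 1146×716
pinhole with a 75° horizontal FoV — a design choice of this package. The
true extrinsics (a few centimeters of baseline with slight toe-in) are
likewise plausible placements, not measured values; no ground-truth rig
geometry exists to reproduce, so all accuracy statements are about
recovering the *simulator's* truth.

The phantom is a head ellipsoid (~9 cm), torso ellipsoid (~22 cm), and a
1 cm nose sphere protruding from the face, each with a flat RGB color
and thermal level; the head box includes the nose silhouette. What the
simulator does **not** emulate: lens distortion in the rendered views
(distortion is exercised synthetically in unit tests instead), thermal
noise textures, motion blur, phototherapy lighting, specularity,
multipath ToF artifacts, and soft occluders. Passing tests therefore
demonstrate geometric and algorithmic correctness of the pipeline, not
robustness to clinical image conditions.

## Numerical choices and problem sizes

Distortion inversion is a 20-step fixed-point iteration (ample for
moderate lens coefficients). Planarity threshold 1e-4 on the singular-
value ratio; LM tolerances 1e-14. Blob centers are contrast-weighted
centroids of connected components filtered by area and Crofton-perimeter
circularity ≥ 0.7 (small rendered circles — 5–9 px diameter at working
distance — make polygonal perimeter estimates too noisy). The recovery
study uses 50 random board placements (rotation magnitude ≤ 0.6 rad,
distance 0.3–1 m, 120 correspondences); the noise study 20 seeds at
σ = 0.5 px, where the expected residual RMS ≈ σ·√(2 − 12/n) ≈ 0.7 px
sits comfortably inside the asserted [0.2, 1.0] px band. These sizes
are the package's standing study conditions and keep the full suite at
about a minute on one CPU.

## Known limitations

Rendered-image calibration is quantization-limited: rounding ToF blob
centers to integer mono pixels before the cloud lookup biases the 3D
side by up to half a ToF pixel, bounding translation recovery to the
millimeter level (geometry-only correspondences recover to ~1e-15). The
per-subject refinement of correspondences is supported only as a
user-supplied CSV of extra pairs, not automated. Fisheye optics,
intrinsic estimation, network training, and temporal stream matching are
out of scope.
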