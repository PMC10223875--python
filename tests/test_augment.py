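"""Bounding-box-aware augmentation: geometry, retention rules, determinism."""

import numpy as np
import pytest

from tofusion.annotations import BBox
from tofusion.augment import (
    OPERATOR_NAMES,
    AnnotatedFrame,
    AugmentationPlan,
    add_noise,
    adjust_contrast,
    adjust_saturation_brightness,
    apply_operator,
    augment_dataset,
    blur_or_sharpen,
    equalize_histogram,
    mirror,
    random_crop,
    random_erase,
    rotate90_resize,
    zoom_center,
)


@pytest.fixture
def gray_frame():
    rng = np.random.default_rng(42)
    return AnnotatedFrame(
        image=rng.integers(0, 255, (480, 640), dtype=np.uint8),
        boxes=[BBox("head", 100, 80, 220, 200), BBox("torso", 300, 200, 500, 420)],
    )


@pytest.fixture
def rgb_frame():
    rng = np.random.default_rng(43)
    return AnnotatedFrame(
        image=rng.integers(0, 255, (716, 1146, 3), dtype=np.uint8),
        boxes=[BBox("head", 400, 200, 700, 500)],
        modality="rgb",
    )


class TestMirror:
    @pytest.mark.parametrize("axis", ["x", "y", "both"])
    def test_involution_bit_exact(self, gray_frame, axis):
        twice = mirror(mirror(gray_frame, axis), axis)
        assert np.array_equal(twice.image, gray_frame.image)
        for a, b in zip(twice.boxes, gray_frame.boxes):
            assert a == b

    def test_box_remap_closed_form(self):
        f = AnnotatedFrame(
            image=np.zeros((50, 100), np.uint8), boxes=[BBox("head", 10, 20, 30, 40)]
        )
        out = mirror(f, "x")
        b = out.boxes[0]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (70, 20, 90, 40)

    def test_pixels_match_index_reversal(self, gray_frame):
        assert np.array_equal(
            mirror(gray_frame, "x").image, gray_frame.image[:, ::-1]
        )
        assert np.array_equal(
            mirror(gray_frame, "y").image, gray_frame.image[::-1, :]
        )


class TestRotate90:
    def test_four_quarter_turns_box_identity(self, gray_frame):
        f = gray_frame
        for _ in range(4):
            f = rotate90_resize(f, 1)
        for a, b in zip(f.boxes, gray_frame.boxes):
            assert abs(a.x_min - b.x_min) < 1.0
            assert abs(a.y_min - b.y_min) < 1.0
            assert abs(a.x_max - b.x_max) < 1.0
            assert abs(a.y_max - b.y_max) < 1.0

    def test_output_keeps_frame_size(self, gray_frame, rgb_frame):
        assert rotate90_resize(gray_frame, 1).image.shape == (480, 640)
        assert rotate90_resize(rgb_frame, 3).image.shape == (716, 1146, 3)

    def test_half_turn_is_exact_involution(self, gray_frame):
        twice = rotate90_resize(rotate90_resize(gray_frame, 2), 2)
        assert np.array_equal(twice.image, gray_frame.image)

    def test_box_centroid_matches_affine_oracle(self, gray_frame):
        W, H = 640, 480
        out = rotate90_resize(gray_frame, 1)
        for b_in, b_out in zip(gray_frame.boxes, out.boxes):
            corners = np.array(
                [
                    [b_in.x_min, b_in.y_min], [b_in.x_max, b_in.y_min],
                    [b_in.x_min, b_in.y_max], [b_in.x_max, b_in.y_max],
                ]
            )
            # CCW quarter-turn on a WxH canvas, then scale (H,W) -> (W,H)
            mapped = np.stack(
                [corners[:, 1] * (W / H), (W - corners[:, 0]) * (H / W)], axis=1
            )
            assert b_out.x_min == pytest.approx(mapped[:, 0].min(), abs=1e-9)
            assert b_out.y_max == pytest.approx(mapped[:, 1].max(), abs=1e-9)


class TestZoom:
    def test_identity_factor(self, gray_frame):
        out = zoom_center(gray_frame, 1.0)
        assert np.array_equal(out.image, gray_frame.image)
        assert out.boxes == gray_frame.boxes

    def test_half_factor_centered_box(self):
        f = AnnotatedFrame(
            image=np.zeros((100, 200), np.uint8),
            boxes=[BBox("head", 80, 30, 120, 70)],  # centered at (100, 50)
        )
        b = zoom_center(f, 0.5).boxes[0]
        assert (b.x_min, b.y_min, b.x_max, b.y_max) == (90, 40, 110, 60)

    def test_box_corners_match_affine_oracle(self, gray_frame):
        factor = 1.3
        out = zoom_center(gray_frame, factor)
        W, H = 640, 480
        for b_in, b_out in zip(gray_frame.boxes, out.boxes):
            x0 = W / 2 + (b_in.x_min - W / 2) * factor
            y1 = H / 2 + (b_in.y_max - H / 2) * factor
            assert b_out.x_min == pytest.approx(max(x0, 0), abs=1e-9)
            assert b_out.y_max == pytest.approx(min(y1, H), abs=1e-9)

    def test_zoom_out_pads_black(self, gray_frame):
        out = zoom_center(gray_frame, 0.5)
        assert out.image[0, 0] == 0 and out.image[-1, -1] == 0


class TestRandomCrop:
    def test_full_image_crop_is_identity(self, gray_frame):
        out = random_crop(gray_frame, rect=(0, 0, 640, 480))
        assert np.array_equal(out.image, gray_frame.image)
        assert out.boxes == gray_frame.boxes

    def test_75_percent_boundary(self):
        # box (0,0,100,100); crop covering exactly 75 columns -> kept
        f = AnnotatedFrame(
            image=np.zeros((200, 200), np.uint8), boxes=[BBox("head", 0, 0, 100, 100)]
        )
        kept = random_crop(f, rect=(25, 0, 175, 200))
        assert len(kept.boxes) == 1
        # 74.9% visible -> discarded (crop from x=25.1 impossible with int
        # rect, so shrink the crop one step below the boundary instead)
        gone = random_crop(f, rect=(26, 0, 174, 200))
        assert len(gone.boxes) == 0

    def test_content_moves_to_top_left(self, gray_frame):
        out = random_crop(gray_frame, rect=(100, 50, 200, 150))
        assert np.array_equal(
            out.image[:150, :200], gray_frame.image[50:200, 100:300]
        )
        assert np.all(out.image[150:, :] == 0)
        assert np.all(out.image[:, 200:] == 0)

    def test_decisions_match_area_oracle(self, gray_frame):
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x0 = int(rng.integers(0, 321))
            y0 = int(rng.integers(0, 241))
            w = int(rng.integers(160, 640 - x0 + 1))
            h = int(rng.integers(120, 480 - y0 + 1))
            out = random_crop(gray_frame, rect=(x0, y0, w, h))
            expected = 0
            for b in gray_frame.boxes:
                ix = max(0.0, min(b.x_max, x0 + w) - max(b.x_min, x0))
                iy = max(0.0, min(b.y_max, y0 + h) - max(b.y_min, y0))
                if ix * iy / b.area >= 0.75:
                    expected += 1
            assert len(out.boxes) == expected


class TestRandomErase:
    def test_no_rects_leaves_frame(self, gray_frame):
        out = random_erase(gray_frame, rects=[])
        assert np.array_equal(out.image, gray_frame.image)
        assert len(out.boxes) == 2

    def test_50_percent_boundary(self):
        f = AnnotatedFrame(
            image=np.full((100, 100), 99, np.uint8),
            boxes=[BBox("head", 0, 0, 100, 100)],
        )
        # exactly 50% covered -> kept
        assert len(random_erase(f, rects=[(0, 0, 100, 50)]).boxes) == 1
        # 50.1% covered -> discarded
        assert len(random_erase(f, rects=[(0, 0, 100, 50.1)]).boxes) == 0

    def test_decisions_match_pixel_mask_oracle(self):
        rng_master = np.random.default_rng(77)
        f = AnnotatedFrame(
            image=np.full((120, 160), 50, np.uint8),
            boxes=[BBox("head", 20, 30, 80, 90), BBox("torso", 90, 10, 150, 110)],
        )
        for _ in range(100):
            rects = []
            for _ in range(int(rng_master.integers(1, 4))):
                x0 = int(rng_master.integers(0, 140))
                y0 = int(rng_master.integers(0, 100))
                rects.append(
                    (x0, y0, x0 + int(rng_master.integers(5, 60)),
                     y0 + int(rng_master.integers(5, 60)))
                )
            out = random_erase(f, rects=rects)
            mask = np.zeros((120, 160), bool)
            for x0, y0, x1, y1 in rects:
                mask[y0:min(y1, 120), x0:min(x1, 160)] = True
            expected = []
            for b in f.boxes:
                cov = mask[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)]
                if cov.mean() <= 0.5:
                    expected.append(b.label)
            assert [b.label for b in out.boxes] == expected


class TestPhotometric:
    def test_zero_noise_identity(self, gray_frame):
        rng = np.random.default_rng(0)
        out = add_noise(gray_frame, "salt_pepper", rng, fraction=0.0)
        assert np.array_equal(out.image, gray_frame.image)
        out = add_noise(gray_frame, "gaussian", rng, sigma=0.0)
        assert np.array_equal(out.image, gray_frame.image)

    def test_salt_pepper_fraction_binomial(self):
        img = np.full((480, 640), 128, np.uint8)
        f = AnnotatedFrame(image=img)
        N, p = 480 * 640, 0.02
        counts = [
            int(
                (add_noise(f, "salt_pepper", np.random.default_rng(s),
                           fraction=p).image != 128).sum()
            )
            for s in range(20)
        ]
        assert abs(np.mean(counts) - p * N) < 3 * np.sqrt(N * p * (1 - p))

    def test_boxes_never_change(self, gray_frame, rgb_frame):
        rng = np.random.default_rng(1)
        for out in [
            add_noise(gray_frame, "gaussian", rng),
            adjust_contrast(gray_frame, 0.6),
            adjust_saturation_brightness(rgb_frame, 0.3),
            blur_or_sharpen(gray_frame, "blur", sigma=2.5),
            blur_or_sharpen(gray_frame, "sharpen", rng),
            equalize_histogram(rgb_frame),
        ]:
            ref = gray_frame.boxes if out.modality != "rgb" else rgb_frame.boxes
            assert out.boxes == ref

    def test_contrast_constant_image(self):
        f = AnnotatedFrame(image=np.full((10, 10), 100, np.uint8))
        assert np.all(adjust_contrast(f, 0.6).image == 60)

    def test_contrast_halves_mean(self, gray_frame):
        out = adjust_contrast(gray_frame, 0.5)
        assert abs(out.image.mean() - gray_frame.image.mean() / 2) < 0.5

    def test_contrast_matches_elementwise_oracle(self, gray_frame):
        c = 0.685
        out = adjust_contrast(gray_frame, c)
        oracle = np.clip(np.rint(gray_frame.image.astype(float) * c), 0, 255)
        assert np.array_equal(out.image, oracle.astype(np.uint8))

    def test_saturation_gain_on_gray_pixel(self):
        from skimage.color import rgb2hsv

        img = np.full((4, 4, 3), 120, np.uint8)
        out = adjust_saturation_brightness(AnnotatedFrame(image=img), 0.25)
        hsv = rgb2hsv(out.image)
        assert np.allclose(hsv[..., 1], 0.25, atol=0.02)

    def test_saturation_zero_shift_round_trips(self, rgb_frame):
        out = adjust_saturation_brightness(rgb_frame, 0.0)
        assert np.max(
            np.abs(out.image.astype(int) - rgb_frame.image.astype(int))
        ) <= 1

    def test_blur_preserves_constants(self):
        f = AnnotatedFrame(image=np.full((32, 32), 77, np.uint8))
        assert np.all(blur_or_sharpen(f, "blur", sigma=3.0).image == 77)

    def test_blur_impulse_is_unit_mass_gaussian(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = blur_or_sharpen(AnnotatedFrame(image=img), "blur", sigma=2.5)
        assert out.image.sum() == pytest.approx(1.0, abs=1e-6)
        assert out.image[32, 32] == out.image.max()

    def test_sharpen_matches_convolution_oracle(self, gray_frame):
        from scipy.ndimage import convolve

        kernel = np.array([[0.1, -0.3, 0.2], [-0.5, 1.9, -0.4], [0.3, -0.2, -0.1]])
        out = blur_or_sharpen(gray_frame, "sharpen", kernel=kernel)
        oracle = np.clip(
            np.rint(convolve(gray_frame.image.astype(float), kernel, mode="reflect")),
            0, 255,
        ).astype(np.uint8)
        assert np.array_equal(out.image, oracle)

    def test_equalize_uniform_luma_unchanged(self):
        # luma already uniform over the full range: mapping is ~identity
        img = np.tile(np.arange(256, dtype=np.uint8), (16, 1))
        out = equalize_histogram(AnnotatedFrame(image=img))
        assert np.max(np.abs(out.image.astype(int) - img.astype(int))) <= 1

    def test_equalize_improves_cdf_uniformity(self):
        img = np.zeros((64, 64), np.uint8)
        img[:, 32:] = 110
        img[:16, :] = 90
        out = equalize_histogram(AnnotatedFrame(image=img))

        def ks_to_uniform(a):
            v = np.sort(a.ravel()) / 255.0
            ecdf = np.arange(1, v.size + 1) / v.size
            return np.max(np.abs(ecdf - v))

        assert ks_to_uniform(out.image) < ks_to_uniform(img)

    def test_equalize_preserves_chroma(self, rgb_frame):
        from skimage.color import rgb2ycbcr

        out = equalize_histogram(rgb_frame)
        before = rgb2ycbcr(rgb_frame.image.astype(float) / 255.0)
        after = rgb2ycbcr(out.image.astype(float) / 255.0)
        # chroma untouched wherever the luma shift kept the pixel in gamut
        # (gamut clipping at 0/255 necessarily bends chroma; exclude it)
        in_gamut = np.all((out.image > 0) & (out.image < 255), axis=-1)
        diff = np.abs(before[..., 1:] - after[..., 1:])[in_gamut]
        assert in_gamut.mean() > 0.5
        assert np.max(diff) <= 1.5


class TestDatasetLevel:
    def test_operator_count_conservation(self, gray_frame):
        frames = [gray_frame] * 10
        out, recs = augment_dataset(frames, AugmentationPlan(("mirror",), seed=1))
        assert len(out) == 10 and len(recs) == 10

    def test_one_to_one_corpus_ratio(self, gray_frame):
        # paper-style 1:1 augmentation: n inputs -> n outputs
        frames = [gray_frame] * 14
        out, _ = augment_dataset(frames, AugmentationPlan(("random",), seed=3))
        assert len(out) == len(frames)

    def test_seeded_rerun_is_byte_identical(self, gray_frame, rgb_frame):
        frames = [gray_frame, rgb_frame]
        plan = AugmentationPlan(("random", "random"), seed=123)
        a, ra = augment_dataset(frames, plan)
        b, rb = augment_dataset(frames, plan)
        assert ra == rb
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert x.boxes == y.boxes

    def test_every_operator_preserves_dims_and_box_validity(self, rgb_frame):
        for name in OPERATOR_NAMES:
            out, _ = apply_operator(name, rgb_frame, np.random.default_rng(5))
            assert out.image.shape == rgb_frame.image.shape
            for b in out.boxes:
                assert 0 <= b.x_min < b.x_max <= out.width
                assert 0 <= b.y_min < b.y_max <= out.height
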