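import numpy as np
import pytest

from lesionfuse import synthfixtures as sf
from lesionfuse.hairremoval import (
    HairMask,
    HairRemovalParams,
    closing_response,
    detect_hair_mask,
    inpaint_bilinear,
    remove_hair,
    smooth_replaced,
    verify_hair_structure,
)
from lesionfuse.preprocess import DermoscopyImage, GrayImage, to_grayscale

PARAMS = HairRemovalParams()


def _gray(arr):
    return GrayImage(pixels=np.asarray(arr, dtype=np.uint8))


class TestClosingResponse:
    def test_uniform_image_zero_response(self):
        resp = closing_response(_gray(np.full((30, 30), 90)), PARAMS)
        assert (resp == 0).all()

    def test_dark_line_response_equals_contrast(self):
        px = np.full((21, 21), 200, dtype=np.uint8)
        px[10, :] = 20
        resp = closing_response(_gray(px), PARAMS)
        # interior line pixels: some SE orientation bridges the dark line
        assert (resp[10, 5:16] == 180).all()

    def test_bright_line_gives_no_response(self):
        px = np.full((21, 21), 50, dtype=np.uint8)
        px[10, :] = 230
        resp = closing_response(_gray(px), PARAMS)
        assert (resp[10, :] == 0).all()

    def test_oversized_se_rejected(self):
        with pytest.raises(ValueError):
            closing_response(
                _gray(np.zeros((10, 10))), HairRemovalParams(se_lengths=(21,))
            )


class TestVerifyStructure:
    def test_empty_mask_stays_empty(self):
        m = verify_hair_structure(HairMask(np.zeros((20, 20), bool)), PARAMS)
        assert m.count() == 0

    def test_long_segment_kept(self):
        px = np.zeros((50, 50), bool)
        px[25, 5:45] = True  # 40x1 segment
        kept = verify_hair_structure(
            HairMask(px), HairRemovalParams(min_length=20, min_elongation=3)
        )
        assert kept.count() == 40

    def test_small_square_removed(self):
        px = np.zeros((50, 50), bool)
        px[10:15, 10:15] = True
        kept = verify_hair_structure(
            HairMask(px), HairRemovalParams(min_length=20, min_elongation=3)
        )
        assert kept.count() == 0

    def test_compact_disk_excluded_from_detection(self):
        px = np.full((60, 60), 200, dtype=np.uint8)
        yy, xx = np.mgrid[0:60, 0:60]
        px[(yy - 30) ** 2 + (xx - 30) ** 2 <= 7.5**2] = 40  # diameter-15 dark disk
        assert detect_hair_mask(_gray(px), PARAMS).count() == 0

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(3)
        px = rng.random((40, 40)) < 0.2
        out = verify_hair_structure(HairMask(px), PARAMS)
        assert not np.any(out.pixels & ~px)


class TestInpaint:
    def test_empty_mask_is_identity(self, flat_image):
        mask = HairMask(np.zeros((40, 56), bool))
        assert np.array_equal(inpaint_bilinear(flat_image, mask).pixels, flat_image.pixels)

    def test_masked_line_on_ramp_recovers_true_values(self):
        ramp = np.tile(np.arange(0, 200, 4, dtype=np.uint8), (30, 1))
        img = DermoscopyImage(pixels=np.stack([ramp] * 3, axis=-1))
        mask = np.zeros((30, 50), bool)
        mask[:, 25] = True  # vertical masked line across horizontal ramp
        out = inpaint_bilinear(img, HairMask(mask))
        assert np.array_equal(out.pixels[:, 25], img.pixels[:, 25])
        assert np.array_equal(out.pixels[:, :25], img.pixels[:, :25])

    def test_fully_masked_image_errors(self, flat_image):
        with pytest.raises(ValueError, match="donor"):
            inpaint_bilinear(flat_image, HairMask(np.ones((40, 56), bool)))


class TestSmoothReplaced:
    def test_empty_mask_is_identity(self, flat_image):
        out = smooth_replaced(flat_image, HairMask(np.zeros((40, 56), bool)), PARAMS)
        assert np.array_equal(out.pixels, flat_image.pixels)

    def test_masked_outlier_takes_neighborhood_median(self):
        px = np.full((20, 20, 3), 100, dtype=np.uint8)
        px[10, 10] = 255
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        out = smooth_replaced(DermoscopyImage(pixels=px), HairMask(mask), PARAMS)
        assert (out.pixels[10, 10] == 100).all()

    def test_uniform_image_unchanged_under_any_mask(self, flat_image):
        rng = np.random.default_rng(5)
        mask = HairMask(rng.random((40, 56)) < 0.3)
        out = smooth_replaced(flat_image, mask, PARAMS)
        assert np.array_equal(out.pixels, flat_image.pixels)


class TestRemoveHair:
    def test_hairless_image_untouched(self, small_nevus):
        img, _, _ = small_nevus
        cleaned, mask = remove_hair(img)
        # texture noise may trigger a few isolated detections at most
        assert mask.count() / mask.pixels.size < 0.01
        untouched = ~mask.pixels
        assert np.array_equal(cleaned.pixels[untouched], img.pixels[untouched])

    def test_pixels_outside_mask_never_modified(self, small_melanoma):
        img, _, _ = small_melanoma
        hairy, _ = sf.overlay_hair(img, 4, thickness=2, seed=11)
        cleaned, mask = remove_hair(hairy)
        outside = ~mask.pixels
        assert np.array_equal(cleaned.pixels[outside], hairy.pixels[outside])

    def test_detection_and_inpainting_on_generated_strokes(self, small_melanoma):
        img, _, _ = small_melanoma
        hairy, truth = sf.overlay_hair(img, 5, thickness=2, seed=11)
        detected = detect_hair_mask(to_grayscale(hairy))
        tp = np.logical_and(detected.pixels, truth.pixels).sum()
        assert tp / truth.count() >= 0.8  # recall
        assert tp / detected.count() >= 0.5  # precision
        cleaned, _ = remove_hair(hairy)
        on = truth.pixels
        mae_before = np.abs(hairy.pixels[on].astype(float) - img.pixels[on]).mean()
        mae_after = np.abs(cleaned.pixels[on].astype(float) - img.pixels[on]).mean()
        assert mae_after <= 0.5 * mae_before

    def test_pen_mark_removed_like_hair(self, small_nevus):
        img, lesion_mask, _ = small_nevus
        # a short dark arc near (not on) the lesion, like a dermatologist mark
        px = img.pixels.copy()
        h, w = px.shape[:2]
        t = np.linspace(-0.6, 0.6, 200)
        rr = np.clip((h * 0.12 + 18 * t**2).astype(int), 0, h - 1)
        cc = np.clip((w * 0.5 + w * 0.3 * t).astype(int), 0, w - 1)
        for dr in (0, 1):
            px[rr + dr, cc] = (30, 22, 40)
        marked = DermoscopyImage(pixels=px)
        cleaned, mask = remove_hair(marked)
        assert mask.pixels[rr, cc].mean() >= 0.8  # mark detected
        on = np.zeros((h, w), bool)
        on[rr, cc] = True
        mae_before = np.abs(px[on].astype(float) - img.pixels[on]).mean()
        mae_after = np.abs(cleaned.pixels[on].astype(float) - img.pixels[on]).mean()
        assert mae_after < 0.5 * mae_before


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"se_lengths": (2,)},
            {"se_angles": (180.0,)},
            {"detect_threshold": 0},
            {"min_elongation": 1.0},
            {"median_window": 4},
            {"max_width": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            HairRemovalParams(**kw)
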