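"""Discriminant index, segmentation, cover ratio, image I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from PIL import Image

from canopydx.errors import ImageReadError, InputDomainError, UnsupportedImageError
from canopydx.imaging import (
    CanopySegmenter,
    cover_ratio,
    discriminant_index,
    load_image,
    save_mask,
    segment,
)

channel = st.integers(min_value=0, max_value=255)


class TestDiscriminantIndex:
    @pytest.mark.parametrize(
        "r, g, expected",
        [
            (100, 100, 128.0),          # gray is neutral
            (0, 255, 256.0),            # pure green hits the top
            (255, 0, 0.0),              # pure red hits the bottom
            (50, 100, 128 + 128 * 50 / 150),
            (61, 67, 134.0),            # exactly at the threshold
            (0, 0, 128.0),              # black: defined neutral
        ],
    )
    def test_known_values(self, r, g, expected):
        assert discriminant_index(r, g) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        r = np.array([[100, 0], [255, 61]])
        g = np.array([[100, 255], [0, 67]])
        out = discriminant_index(r, g)
        assert out.shape == (2, 2)
        np.testing.assert_allclose(out, [[128, 256], [0, 134]])

    @pytest.mark.parametrize("r, g", [(-1, 0), (0, 256), (300, 10)])
    def test_out_of_range_rejected(self, r, g):
        with pytest.raises(InputDomainError):
            discriminant_index(r, g)

    @given(r=channel, g=channel)
    def test_antisymmetry(self, r, g):
        # I(r, g) + I(g, r) == 256 whenever r + g > 0
        if r + g > 0:
            assert discriminant_index(r, g) + discriminant_index(g, r) == pytest.approx(
                256.0, abs=1e-9
            )

    @given(r=channel, g1=channel, g2=channel)
    def test_monotone_in_green(self, r, g1, g2):
        lo, hi = sorted((g1, g2))
        assert discriminant_index(r, lo) <= discriminant_index(r, hi) + 1e-12

    @given(v=channel)
    def test_gray_neutrality(self, v):
        assert discriminant_index(v, v) == 128.0
        pixel = np.full((1, 1, 3), v, dtype=np.uint8)
        assert not segment(pixel).any()


class TestSegment:
    def test_uniform_gray_is_background(self, gray_image):
        assert not segment(gray_image).any()

    @pytest.mark.parametrize(
        "pixel, expected",
        [
            ((0, 255, 0), True),     # saturated green
            ((61, 67, 200), True),   # I = 134 exactly: inclusive boundary
            ((62, 67, 0), False),    # I ~ 132.96, just below
        ],
    )
    def test_single_pixel_classification(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert segment(img)[0, 0] == expected

    def test_blue_channel_ignored(self):
        base = np.array([[[61, 67, 0]]], dtype=np.uint8)
        for b in (0, 128, 255):
            img = base.copy()
            img[0, 0, 2] = b
            assert segment(img)[0, 0]

    def test_matches_per_pixel_oracle_on_random_image(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(20, 30, 3), dtype=np.uint8)
        mask = segment(img)
        for i in range(20):
            for j in range(30):
                r, g = int(img[i, j, 0]), int(img[i, j, 1])
                idx = 128.0 + 128.0 * (g - r) / (g + r) if r + g else 128.0
                assert mask[i, j] == (idx >= 134.0)

    def test_rejects_bad_shapes(self):
        with pytest.raises(InputDomainError):
            segment(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(InputDomainError):
            segment(np.zeros((5, 5, 4), dtype=np.uint8))


class TestCoverRatio:
    @pytest.mark.parametrize(
        "true_count, expected",
        [(100, 100.0), (25, 25.0), (0, 0.0)],
    )
    def test_counts(self, true_count, expected):
        mask = np.zeros(100, dtype=bool)
        mask[:true_count] = True
        result = cover_ratio(mask.reshape(10, 10))
        assert result.cover_percent == expected
        assert result.vegetation_pixels == true_count
        assert result.total_pixels == 100

    def test_exact_fraction(self):
        # 100k/N with no floating-point surprises at these sizes
        mask = np.zeros((7, 13), dtype=bool)
        mask.ravel()[:17] = True
        assert cover_ratio(mask).cover_percent == 100 * 17 / 91

    def test_empty_and_nonbool_rejected(self):
        with pytest.raises(InputDomainError):
            cover_ratio(np.zeros((0, 5), dtype=bool))
        with pytest.raises(InputDomainError):
            cover_ratio(np.zeros((5, 5), dtype=np.uint8))


class TestImageIO:
    def test_png_round_trip(self, write_png):
        rng = np.random.default_rng(1)
        original = rng.integers(0, 256, size=(2, 2, 3), dtype=np.uint8)
        loaded = load_image(write_png(original))
        np.testing.assert_array_equal(loaded, original)

    def test_grayscale_promoted(self, tmp_path):
        path = tmp_path / "gray.png"
        Image.fromarray(np.full((4, 4), 120, dtype=np.uint8), mode="L").save(path)
        arr = load_image(path)
        assert arr.shape == (4, 4, 3)
        assert (arr == 120).all()

    def test_alpha_dropped(self, tmp_path):
        path = tmp_path / "rgba.png"
        rgba = np.zeros((3, 3, 4), dtype=np.uint8)
        rgba[..., 1] = 200
        rgba[..., 3] = 128
        Image.fromarray(rgba, mode="RGBA").save(path)
        arr = load_image(path)
        assert arr.shape == (3, 3, 3)
        assert (arr[..., 1] == 200).all()

    def test_truncated_file_raises(self, tmp_path, write_png):
        good = write_png(np.zeros((50, 50, 3), dtype=np.uint8))
        bad = tmp_path / "trunc.png"
        bad.write_bytes(good.read_bytes()[:40])
        with pytest.raises(ImageReadError):
            load_image(bad)

    def test_sixteen_bit_rejected(self, tmp_path):
        path = tmp_path / "deep.png"
        Image.new("I;16", (4, 4), 0).save(path)
        with pytest.raises(UnsupportedImageError):
            load_image(path)

    def test_mask_export_white_on_black(self, tmp_path):
        mask = np.array([[True, False], [False, True]])
        path = tmp_path / "mask.png"
        save_mask(mask, path)
        out = np.asarray(Image.open(path))
        np.testing.assert_array_equal(out, [[255, 0], [0, 255]])


class TestCanopySegmenter:
    def test_transform_equals_function(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(15, 15, 3), dtype=np.uint8)
        np.testing.assert_array_equal(CanopySegmenter().fit().transform(img), segment(img))

    def test_threshold_param_travels_through_sklearn_api(self):
        from sklearn.base import clone

        seg = CanopySegmenter(threshold=150)
        assert clone(seg).get_params()["threshold"] == 150
        seg.set_params(threshold=128.5)
        img = np.array([[[100, 105, 0]]], dtype=np.uint8)  # I ~ 131.1
        assert seg.fit().transform(img)[0, 0]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InputDomainError):
            CanopySegmenter(threshold=300).fit()
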