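"""Grayscale conversion and histogram segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.draw import disk

from cariescan import (
    compute_segmentation,
    otsu_threshold,
    segment_discoloration,
    segment_surface,
    segment_tooth,
    to_gray8,
)
from cariescan.image import load_mask, save_mask

from conftest import naive_otsu


class TestToGray8:
    @pytest.mark.parametrize(
        "value,expected",
        [(0, 0), (255, 255), (128, 128)],
        ids=["black", "white", "mid-gray"],
    )
    def test_uniform_rgb_maps_to_luma(self, value, expected):
        img = np.full((5, 7, 3), value, dtype=np.uint8)
        out = to_gray8(img)
        assert out.dtype == np.uint8
        assert (out == expected).all()

    def test_float_input_interpreted_on_unit_range(self):
        out = to_gray8(np.full((3, 3), 0.5))
        assert (out == 128).all()  # 127.5 rounds half-up

    def test_gray_uint8_passthrough(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert (to_gray8(img) == img).all()

    def test_alpha_channel_dropped(self):
        rgba = np.dstack([np.full((4, 4), 200, np.uint8)] * 3 + [np.zeros((4, 4), np.uint8)])
        assert (to_gray8(rgba) == 200).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            to_gray8(np.zeros((0, 3)))
        with pytest.raises(ValueError, match="channel"):
            to_gray8(np.zeros((4, 4, 2), np.uint8))


class TestOtsu:
    def test_two_level_image_splits_at_valley(self):
        vals = np.array([10] * 50 + [200] * 50, np.uint8)
        t = otsu_threshold(vals)
        assert 10 <= t < 200

    def test_matches_exhaustive_search_on_random_images(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
            assert otsu_threshold(img) == naive_otsu(img)

    def test_degenerate_histogram_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full(100, 77, np.uint8))


class TestSegmentSurface:
    def test_bright_disc_recovered_exactly(self):
        img = np.zeros((64, 64), np.uint8)
        rr, cc = disk((32, 32), 20)
        img[rr, cc] = 200
        res = segment_surface(img)
        assert (res.mask == (img == 200)).all()
        assert 0 <= res.threshold < 200

    def test_auto_threshold_equals_oracle(self, rng):
        for _ in range(5):
            img = np.concatenate(
                [rng.normal(60, 15, 800), rng.normal(190, 20, 600)]
            ).clip(0, 255)
            img = img.astype(np.uint8).reshape(35, 40)
            res = segment_surface(img)
            assert res.threshold == naive_otsu(img)

    def test_manual_threshold_full_mask(self):
        img = np.full((8, 8), 150, np.uint8)
        res = segment_surface(img, method="manual", manual_threshold=100)
        assert res.mask.all()
        assert res.threshold == 100

    def test_largest_component_kept_and_holes_filled(self):
        img = np.zeros((40, 40), np.uint8)
        img[5:25, 5:25] = 200  # big square
        img[12:18, 12:18] = 10  # dark hole inside it
        img[30:33, 30:33] = 200  # small distractor blob
        res = segment_surface(img)
        assert res.mask[13, 13]  # hole filled
        assert not res.mask[31, 31]  # distractor dropped

    def test_uniform_auto_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            segment_surface(np.full((8, 8), 99, np.uint8))


class TestSegmentDiscoloration:
    def _surface_with_line(self):
        img = np.full((32, 32), 200, np.uint8)
        surface = np.zeros((32, 32), bool)
        surface[4:28, 4:28] = True
        img[~surface] = 0
        img[16, 6:26] = 30
        return img, surface

    def test_dark_line_recovered_exactly(self):
        img, surface = self._surface_with_line()
        res = segment_discoloration(img, surface)
        assert (res.mask == (surface & (img == 30))).all()

    def test_mask_is_subset_of_surface(self, rng):
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        surface = np.zeros((24, 24), bool)
        surface[3:21, 3:21] = True
        res = segment_discoloration(img, surface)
        assert not (res.mask & ~surface).any()

    def test_no_pixel_below_manual_threshold_gives_empty_mask(self):
        img = np.full((16, 16), 200, np.uint8)
        surface = np.ones((16, 16), bool)
        res = segment_discoloration(img, surface, method="manual", manual_threshold=50)
        assert res.foreground_count == 0

    def test_auto_threshold_matches_surface_restricted_oracle(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
            surface = np.zeros((30, 30), bool)
            surface[5:25, 5:25] = True
            res = segment_discoloration(img, surface)
            assert res.threshold == naive_otsu(img[surface]) + 1
            assert (res.mask == (surface & (img < res.threshold))).all()

    def test_empty_surface_raises(self):
        with pytest.raises(ValueError, match="surface"):
            segment_discoloration(np.zeros((8, 8), np.uint8), np.zeros((8, 8), bool))


class TestComputeSegmentation:
    def test_pa_arithmetic(self):
        surface = np.zeros((40, 40), bool)
        surface[:25, :40] = True  # 1000 px
        disc = np.zeros_like(surface)
        disc[:5, :10] = True  # 50 px
        res = compute_segmentation(surface, disc)
        assert res.surface_area_px == 1000
        assert res.discoloration_area_px == 50
        assert res.pa == 0.05

    @pytest.mark.parametrize("fill", [False, True], ids=["empty->0", "full->1"])
    def test_pa_extremes(self, fill):
        surface = np.ones((10, 10), bool)
        disc = surface.copy() if fill else np.zeros_like(surface)
        assert compute_segmentation(surface, disc).pa == (1.0 if fill else 0.0)

    def test_errors(self):
        surface = np.zeros((4, 4), bool)
        surface[0, 0] = True
        stray = np.zeros((4, 4), bool)
        stray[3, 3] = True
        with pytest.raises(ValueError, match="mask inconsistency"):
            compute_segmentation(surface, stray)
        with pytest.raises(ValueError, match="zero surface"):
            compute_segmentation(np.zeros((4, 4), bool), np.zeros((4, 4), bool))

    @given(
        mask=hnp.arrays(bool, (12, 12), elements=st.booleans()),
        k=st.integers(1, 3),
        rot=st.integers(0, 3),
    )
    def test_pa_invariant_under_rotation_translation_and_scaling(self, mask, k, rot):
        """PA depends only on the area ratio, not pose or resolution."""
        surface = np.ones((12, 12), bool)
        base = compute_segmentation(surface, mask).pa
        rotated = compute_segmentation(np.rot90(surface, rot), np.rot90(mask, rot)).pa
        scaled = compute_segmentation(
            np.kron(surface, np.ones((k, k), bool)), np.kron(mask, np.ones((k, k), bool))
        ).pa
        shifted_s = np.pad(surface, ((2, 0), (0, 2)))
        shifted_m = np.pad(mask, ((2, 0), (0, 2)))
        assert rotated == base
        assert scaled == pytest.approx(base)
        assert compute_segmentation(shifted_s, shifted_m).pa == pytest.approx(base)


def test_mask_png_round_trip(tmp_path):
    """Masks export as 0=foreground / 255=background PNG, bit-exactly."""
    rng = np.random.default_rng(1)
    mask = rng.random((20, 30)) < 0.3
    path = tmp_path / "m.png"
    save_mask(path, mask)
    import PIL.Image

    raw = np.asarray(PIL.Image.open(path))
    assert set(np.unique(raw)) <= {0, 255}
    assert (raw[mask] == 0).all()
    assert (load_mask(path) == mask).all()


def test_segment_tooth_composes_stages():
    img = np.full((64, 64), 30, np.uint8)
    rr, cc = disk((32, 32), 24)
    img[rr, cc] = 200
    img[32, 20:44] = 60
    res = segment_tooth(img)
    assert res.discoloration_area_px == 24
    assert res.pa == pytest.approx(24 / res.surface_area_px)
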