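"""Template matching, Canny, circle Hough and ROI bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.draw import circle_perimeter, disk

from odseg import (
    DEFAULT_HOUGH_RADII,
    LocalizationError,
    TemplateSpec,
    build_disc_template,
    canny_edges,
    extract_roi,
    hough_circle,
    hsi_intensity,
    pearson_match,
)
from oracles import hough_accumulate, pearson_score_map


class TestHsiIntensity:
    def test_equals_per_pixel_channel_mean(self):
        rng = np.random.default_rng(0)
        rgb = rng.random((16, 16, 3))
        expected = np.zeros((16, 16))
        for i in range(16):
            for j in range(16):
                expected[i, j] = (rgb[i, j, 0] + rgb[i, j, 1] + rgb[i, j, 2]) / 3.0
        assert np.allclose(hsi_intensity(rgb), expected, atol=1e-15)

    def test_constant_color(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., :] = (0.9, 0.6, 0.3)
        assert np.allclose(hsi_intensity(rgb), 0.6)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            hsi_intensity(np.zeros((4, 4)))


class TestTemplate:
    def test_default_side_is_401(self):
        assert build_disc_template().shape == (401, 401)

    def test_bright_core_and_radial_symmetry(self):
        t = build_disc_template(TemplateSpec(side=101, core_diameter=60, edge_softness=10))
        assert t[50, 50] > t[0, 0]
        assert np.allclose(t, t.T)
        assert np.allclose(t, t[::-1])
        assert np.allclose(t, t[:, ::-1])

    def test_even_side_rejected(self):
        with pytest.raises(ValueError):
            build_disc_template(TemplateSpec(side=400))


class TestPearsonMatch:
    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(1)
        image = rng.random((64, 64))
        template = rng.random((9, 9))
        scores, _ = pearson_match(image, template)
        assert np.allclose(scores, pearson_score_map(image, template), atol=1e-10)

    def test_perfect_and_affine_matches_score_one(self):
        rng = np.random.default_rng(2)
        template = rng.random((7, 7))
        image = np.zeros((32, 32))
        image[10:17, 5:12] = 2.5 * template + 0.3  # positive affine copy
        scores, argmax = pearson_match(image, template)
        assert scores[10, 5] == pytest.approx(1.0, abs=1e-9)
        assert argmax == (13, 8)  # template center at the match

    def test_constant_windows_score_zero(self):
        template = np.random.default_rng(3).random((9, 9))
        scores, _ = pearson_match(np.full((32, 32), 0.5), template)
        assert np.all(scores == 0.0)

    def test_constant_template_rejected(self):
        with pytest.raises(ValueError):
            pearson_match(np.random.default_rng(4).random((32, 32)), np.ones((5, 5)))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        gain=st.floats(0.1, 10.0, allow_nan=False),
        offset=st.floats(-5.0, 5.0, allow_nan=False),
    )
    def test_score_map_invariant_under_positive_affine_rescaling(self, gain, offset):
        rng = np.random.default_rng(5)
        image = rng.random((40, 40))
        template = rng.random((9, 9))
        base, _ = pearson_match(image, template)
        scaled, _ = pearson_match(gain * image + offset, template)
        assert np.allclose(base, scaled, atol=1e-7)


class TestCanny:
    def test_constant_image_has_no_edges(self):
        assert not canny_edges(np.full((64, 64), 0.3)).any()

    def test_circle_edge_within_two_pixels(self):
        img = np.zeros((128, 128))
        rr, cc = disk((64, 64), 40)
        img[rr, cc] = 1.0
        edges = canny_edges(img, 0.4, sigma=2.0)
        assert edges.sum() > 100
        r = np.hypot(*(np.argwhere(edges) - 64).T)
        assert np.all(np.abs(r - 40) <= 2.0)

    def test_threshold_at_ceiling_nearly_empty(self):
        yy, xx = np.mgrid[0:128, 0:128].astype(float)
        blob = np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 20**2))
        n_max = canny_edges(blob, 1.0).sum()
        assert n_max <= 0.01 * blob.size
        assert n_max <= canny_edges(blob, 0.4).sum()


class TestHoughCircle:
    def test_default_radius_list(self):
        assert DEFAULT_HOUGH_RADII == (140, 155, 170, 185, 200, 215, 230)

    def test_recovers_perfect_circle(self):
        edges = np.zeros((900, 900), dtype=bool)
        rr, cc = circle_perimeter(450, 450, 170)
        edges[rr, cc] = True
        est = hough_circle(edges)
        assert est.center == (450, 450)
        assert est.radius == 170

    def test_matches_brute_force_accumulator(self):
        rng = np.random.default_rng(6)
        edges = np.zeros((96, 96), dtype=bool)
        for center, radius, frac in (((40, 45), 25, 1.0), ((60, 50), 35, 0.6)):
            rr, cc = circle_perimeter(*center, radius, shape=edges.shape)
            keep = rng.random(len(rr)) < frac
            edges[rr[keep], cc[keep]] = True
        edges |= rng.random(edges.shape) < 0.01  # clutter
        radii = [20, 25, 30, 35, 40]
        score, radius, center = hough_accumulate(edges, radii)
        est = hough_circle(edges, radii)
        assert est.center == tuple(center)
        assert est.radius == radius
        assert est.score == pytest.approx(score, abs=1e-9)

    def test_stronger_partial_circle_wins(self):
        edges = np.zeros((128, 128), dtype=bool)
        rr, cc = circle_perimeter(60, 60, 30)
        edges[rr[: int(0.9 * len(rr))], cc[: int(0.9 * len(rr))]] = True
        rr2, cc2 = circle_perimeter(70, 80, 40, shape=edges.shape)
        edges[rr2[: len(rr2) // 2], cc2[: len(cc2) // 2]] = True
        est = hough_circle(edges, [30, 40])
        assert est.radius == 30
        assert np.hypot(est.center[0] - 60, est.center[1] - 60) <= 1.5

    def test_empty_edge_map_raises(self):
        with pytest.raises(LocalizationError, match="edge"):
            hough_circle(np.zeros((64, 64), dtype=bool), [20])


class TestExtractRoi:
    def test_interior_crop_equals_slicing(self):
        img = np.random.default_rng(7).random((1100, 1100))
        roi = extract_roi(img, (550, 560), side=300)
        assert np.array_equal(roi.image, img[400:700, 410:710])
        assert roi.pad == (0, 0)

    def test_corner_center_padded_to_full_side(self):
        img = np.random.default_rng(8).random((200, 200))
        roi = extract_roi(img, (0, 0), side=100)
        assert roi.image.shape == (100, 100)

    def test_coordinate_round_trip(self):
        rng = np.random.default_rng(9)
        img = rng.random((400, 400))
        roi = extract_roi(img, (30, 380), side=200)
        for _ in range(100):
            r, c = int(rng.integers(200)), int(rng.integers(200))
            fr, fc = roi.to_full(r, c)
            if 0 <= fr < 400 and 0 <= fc < 400:
                assert roi.image[r, c] == img[int(fr), int(fc)]


class TestOnFixtures:
    def test_template_match_center_within_25px(self, loc_batch):
        assert max(rec["match_error"] for rec in loc_batch) <= 25.0

    def test_hough_radius_within_one_step_of_mean_semi_axis(self, loc_batch):
        assert max(rec["radius_error"] for rec in loc_batch) <= 15.0
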