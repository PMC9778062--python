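"""Segmentation, filtering and cropping."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import circle_perimeter

from amoxquant import preprocess, synthetic
from amoxquant.preprocess import (
    CircleDetection,
    PreprocessConfig,
    SegmentationError,
    crop_to_square,
    gaussian_filter,
    hough_accumulate,
    hough_detect_circle,
    median_filter,
)
from amoxquant.synthetic import RenderParams, render_well_image, well_geometry


def brute_force_circle(edges, radii):
    """Exhaustive reference search: count edge pixels on every candidate
    circle, same tie-breaking as the production detector (max votes, then
    larger r, then smaller (cy, cx))."""
    h, w = edges.shape
    best = None
    for r in radii:
        dy, dx = circle_perimeter(0, 0, int(r))
        for cy in range(r, h - r):
            for cx in range(r, w - r):
                yy, xx = cy + dy, cx + dx
                votes = int(edges[yy, xx].sum())
                key = (votes, r, -cy, -cx)
                if best is None or key > best:
                    best = key
    votes, r, ncy, ncx = best
    return votes, r, -ncy, -ncx


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((60, 60, 3), 37.0)
        assert np.array_equal(median_filter(img, 5), img)

    def test_center_hot_pixel_suppressed(self):
        img = np.zeros((9, 9, 3))
        img[4, 4, :] = 255.0
        out = median_filter(img, 3)
        assert out[4, 4, 0] == 0.0  # median of nine values, eight of them 0
        assert out.max() == 0.0     # salt noise removed entirely

    @pytest.mark.parametrize("kernel", [2, 4, 1])
    def test_bad_kernel_rejected(self, kernel):
        with pytest.raises(ValueError):
            median_filter(np.zeros((60, 60, 3)), kernel)


class TestGaussianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((55, 55, 3), 123.0)
        out = gaussian_filter(img, 1.0)
        assert np.allclose(out, img, atol=1e-9)

    def test_impulse_response_is_kernel(self):
        img = np.zeros((61, 61, 3))
        img[30, 30, :] = 1.0
        sigma = 1.5
        out = gaussian_filter(img, sigma)[..., 0]
        # direct convolution oracle: outer product of 1-D truncated kernels
        rad = int(3 * sigma + 0.5)
        x = np.arange(-rad, rad + 1)
        k1 = np.exp(-x ** 2 / (2 * sigma ** 2))
        k1 /= k1.sum()
        expected = np.outer(k1, k1)
        window = out[30 - rad:30 + rad + 1, 30 - rad:30 + rad + 1]
        assert np.allclose(window, expected, atol=1e-12)
        assert out.argmax() == 30 * 61 + 30

    def test_variance_never_increases(self, rng):
        img = rng.uniform(0, 255, size=(50, 50, 3))
        out = gaussian_filter(img, 2.0)
        for c in range(3):
            assert out[..., c].var() <= img[..., c].var()

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_filter(np.zeros((50, 50, 3)), 0.0)


class TestHoughDetection:
    def test_matches_exhaustive_search_on_small_fixtures(self, rng):
        """Accumulator argmax equals brute force on <=64x64 edge maps."""
        radii = list(range(8, 13))
        for trial in range(4):
            edges = np.zeros((40, 44), dtype=bool)
            # a genuine circle plus random clutter
            r0 = radii[trial % len(radii)]
            dy, dx = circle_perimeter(20, 21, r0)
            edges[dy, dx] = True
            clutter = rng.integers(0, 40 * 44, size=60)
            edges.flat[clutter] = True

            acc = hough_accumulate(edges, np.array(radii))
            best = None
            for i, r in enumerate(radii):
                votes = int(acc[i].max())
                pos = np.argwhere(acc[i] == votes)
                pos = pos[np.lexsort((pos[:, 1], pos[:, 0]))][0]
                key = (votes, r, -int(pos[0]), -int(pos[1]))
                if best is None or key > best:
                    best = key
            bf = brute_force_circle(edges, radii)
            assert (best[0], best[1], -best[2], -best[3]) == bf

    def test_noise_free_disk_recovered_within_one_pixel(self, clean_render):
        im = render_well_image((150, 70, 140), clean_render, seed=0)
        cx, cy, r = well_geometry(clean_render, 0)
        det = hough_detect_circle(im)
        assert abs(det.cx - cx) <= 1 and abs(det.cy - cy) <= 1
        assert abs(det.r - r) <= 1

    def test_blank_image_raises_segmentation_error(self):
        img = np.full((100, 100, 3), 200.0)
        with pytest.raises(SegmentationError):
            hough_detect_circle(img)

    def test_default_noise_radius_within_two_pixels(self):
        rp = RenderParams()
        im = render_well_image((150, 70, 140), rp, seed=17)
        _, _, r = well_geometry(rp, 17)
        det = hough_detect_circle(im)
        assert abs(det.r - r) <= 2

    def test_geometric_recovery_over_seeded_fixtures(self):
        """Median center error <=1 px and radius error <=2 px, 50 fixtures."""
        rp = RenderParams()
        ec, er = [], []
        for seed in range(50):
            im = render_well_image((150, 70, 140), rp, seed=seed)
            cx, cy, r = well_geometry(rp, seed)
            det = hough_detect_circle(im)
            ec.append(np.hypot(det.cx - cx, det.cy - cy))
            er.append(abs(det.r - r))
        assert np.median(ec) <= 1.0
        assert np.median(er) <= 2.0


class TestCrop:
    def test_output_shape_contract(self, clean_render):
        im = render_well_image((150, 70, 140), clean_render, seed=0)
        det = hough_detect_circle(im)
        out = crop_to_square(im, det, 50)
        assert out.pixels.shape == (50, 50, 3)

    def test_noise_free_disk_crop_is_pure_color(self, clean_render):
        im = render_well_image((150, 70, 140), clean_render, seed=0)
        det = hough_detect_circle(im)
        out = crop_to_square(im, det, 50).pixels
        pure = np.all(np.abs(out - np.array([150, 70, 140])) < 1e-9, axis=-1)
        # corners of the inscribed square touch the rasterized disk rim, so
        # a handful of corner samples may graze background
        assert pure[1:-1, 1:-1].all()
        assert pure.mean() > 0.99

    def test_identity_resampling_on_aligned_grid(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 255, size=(64, 64, 3))
        # r chosen so the inscribed half-side r/sqrt(2) = 10 exactly
        det = CircleDetection(cx=30, cy=32, r=int(np.ceil(10 * np.sqrt(2))), score=1)
        half = det.r / np.sqrt(2)
        size = int(round(2 * half)) + 1
        out = crop_to_square(img, det, size)
        # centers of the sampling grid: compare against direct bilinear oracle
        ys = np.linspace(det.cy - half, det.cy + half, size)
        xs = np.linspace(det.cx - half, det.cx + half, size)
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        ref = np.stack([
            ndimage.map_coordinates(img[..., c], [gy, gx], order=1, mode="nearest")
            for c in range(3)], axis=-1)
        assert np.allclose(out, ref, atol=1e-12)

    def test_out_of_bounds_detection_rejected(self):
        img = np.zeros((60, 60, 3))
        with pytest.raises(ValueError):
            crop_to_square(img, CircleDetection(cx=5, cy=5, r=20, score=1), 50)


class TestFullPreprocess:
    def test_emits_50x50_rgb(self):
        im = render_well_image((150, 70, 140), RenderParams(), seed=4)
        crop, det = preprocess.preprocess(im)
        assert crop.pixels.shape == (50, 50, 3)
        assert det.score > 0

    def test_deterministic(self):
        im = render_well_image((150, 70, 140), RenderParams(), seed=4)
        a, da = preprocess.preprocess(im)
        b, db = preprocess.preprocess(im)
        assert np.array_equal(a.pixels, b.pixels) and da == db

    def test_zero_noise_cropped_mean_equals_disk_color(self, clean_render):
        im = render_well_image((150, 70, 140), clean_render, seed=0)
        crop, _ = preprocess.preprocess(im)
        mean = crop.pixels.reshape(-1, 3).mean(axis=0)
        # Gaussian blur mixes a trace of background at the inscribed-square
        # corners, which touch the disk boundary
        assert np.all(np.abs(mean - np.array([150, 70, 140])) < 2.0)
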