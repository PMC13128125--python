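import numpy as np
import pytest
from skimage import measure

from gutspat import DetectionParams, detect_cells, match_to_truth
from gutspat.detect import (
    DetectionResult,
    classify_regions,
    preprocess,
    segment,
    split_clusters,
)
from gutspat.geometry import PointPattern, Window
from gutspat.synth import DEFAULT_PIXEL_SIZE_UM, render_image

from conftest import separated_pattern

PS = DEFAULT_PIXEL_SIZE_UM
PARAMS = DetectionParams()


def _image(n_cells, seed, n_particles=0, noise=0.0, side_px=512, min_sep=2.0):
    side = side_px * PS
    rng = np.random.default_rng(seed)
    margin = 14.0 if n_particles else 2.0
    pat = separated_pattern(Window.square(side), n_cells, min_sep, rng, margin=margin)
    img = render_image(
        pat,
        cell_radius=0.5,
        noise_sigma=noise,
        pixel_size=PS,
        n_food_particles=n_particles,
        seed=seed,
    )
    return img, pat


class TestPreprocess:
    def test_flat_image_maps_to_zero(self):
        out = preprocess(np.full((64, 64), 3.0), PARAMS, PS)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_ramp_suppressed_blob_preserved(self):
        # background-removal stage: a linear ramp of amplitude 2.0 must be
        # reduced >= 90% while the cell blob's peak survives within 20%
        img, pat = _image(1, seed=0, side_px=256)
        ramp = np.linspace(0, 2.0, 256)[None, :] * np.ones((256, 1))
        out = preprocess(img.pixels + ramp, PARAMS, PS, stretch=False)
        corner = out[:32, -32:]  # far from the blob, high end of the ramp
        assert corner.max() <= 0.1 * 2.0
        iy, ix = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        peak_in = img.pixels[iy, ix]
        assert out[iy, ix] >= 0.8 * peak_in

    def test_stretch_maps_percentile_to_full_scale(self):
        img, _ = _image(5, seed=9, side_px=256)
        raw = preprocess(img.pixels, PARAMS, PS, stretch=False)
        out = preprocess(img.pixels, PARAMS, PS)
        hi = np.percentile(raw, 99.9)
        assert out.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out, np.minimum(raw / hi, 1.0), atol=1e-12)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(1)
        out = preprocess(rng.uniform(0, 1, (64, 64)), PARAMS, PS)
        assert out.min() >= 0

    def test_subpixel_tophat_radius_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((16, 16)), PARAMS, pixel_size=10.0)


class TestSegment:
    def test_blank_image_gives_zero_regions(self):
        _, regions = segment(np.zeros((64, 64)), PARAMS, PS)
        assert regions == []

    def test_three_disjoint_blobs_give_three_regions(self):
        img, _ = _image(3, seed=2, side_px=256, min_sep=5.0)
        filt = preprocess(img.pixels, PARAMS, PS)
        _, regions = segment(filt, PARAMS, PS)
        assert len(regions) == 3

    def test_threshold_monotonicity(self):
        img, _ = _image(5, seed=3, side_px=256)
        filt = preprocess(img.pixels, PARAMS, PS)
        masks = []
        for factor in (1.0, 2.0, 4.0):
            mask, _ = segment(filt, DetectionParams(threshold_factor=factor), PS)
            masks.append(mask.sum())
        assert masks[0] >= masks[1] >= masks[2]


class TestClassify:
    def _fake_region(self, area_px, ecc, sol, aspect, px=1.0):
        class R:  # minimal regionprops stand-in
            pass

        r = R()
        r.area = area_px
        r.eccentricity = ecc
        r.solidity = sol
        r.axis_major_length = aspect
        r.axis_minor_length = 1.0
        return r

    def test_rule_application(self):
        # area in µm² with pixel_size 1: px count is the area
        cell = self._fake_region(0.8, 0.5, 0.95, 1.2)
        particle = self._fake_region(60, 0.99, 0.9, 5.0)
        out = classify_regions([cell, particle], PARAMS, pixel_size=1.0)
        assert out["cells"] == [cell]
        assert out["particles"] == [particle]

    def test_partition_property(self):
        img, _ = _image(15, seed=4, n_particles=2)
        filt = preprocess(img.pixels, PARAMS, PS)
        _, regions = segment(filt, PARAMS, PS)
        out = classify_regions(regions, PARAMS, PS)
        assert sum(len(v) for v in out.values()) == len(regions)
        seen = set()
        for group in out.values():
            for r in group:
                assert id(r) not in seen
                seen.add(id(r))


class TestSplitClusters:
    def _disk_regions(self, centers, R=10, shape=(80, 120)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = np.zeros(shape, bool)
        for cx, cy in centers:
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= R * R
        img = mask.astype(float)
        regions = measure.regionprops(measure.label(mask), intensity_image=img)
        return img, regions

    def test_two_touching_disks_split_to_centers(self):
        # centers 1.5 radii apart; barrier radius above the neck half-width
        img, regions = self._disk_regions([(45, 40), (60, 40)])
        params = DetectionParams(split_dilation_radius=7)
        cents, areas = split_clusters(img, regions, params, pixel_size=0.05)
        assert len(cents) == 2
        got = sorted((c[0] / 0.05 - 0.5, c[1] / 0.05 - 0.5) for c in cents)
        for (gx, gy), (tx, ty) in zip(got, [(45, 40), (60, 40)]):
            assert np.hypot(gx - tx, gy - ty) <= 1.0

    def test_single_blob_yields_single_centroid(self):
        img, regions = self._disk_regions([(60, 40)])
        cents, _ = split_clusters(img, regions, DetectionParams(), pixel_size=0.05)
        assert len(cents) == 1
        assert np.hypot(cents[0][0] / 0.05 - 0.5 - 60, cents[0][1] / 0.05 - 0.5 - 40) <= 1.0

    def test_no_silent_drops(self):
        img, regions = self._disk_regions([(30, 40), (42, 40), (80, 30)])
        cents, _ = split_clusters(
            img, regions, DetectionParams(split_dilation_radius=7), pixel_size=0.05
        )
        assert len(cents) >= len(regions)


class TestDetectCells:
    def test_blank_image_gives_zero_count(self):
        res = detect_cells(np.zeros((128, 128)), PS, PARAMS)
        assert res.total_count == 0

    def test_roundtrip_twenty_cells(self):
        img, pat = _image(20, seed=5)
        res = detect_cells(img.pixels, PS, PARAMS)
        prec, rec, rmse = match_to_truth(res, pat, max_dist=1.0)
        assert prec == 1.0 and rec == 1.0
        assert rmse <= PS  # within one pixel

    def test_particles_counted_and_cells_kept(self):
        img, pat = _image(20, seed=6, n_particles=2)
        res = detect_cells(img.pixels, PS, PARAMS)
        assert res.removed_particles == 2
        prec, rec, _ = match_to_truth(res, pat, max_dist=1.0)
        assert prec == 1.0 and rec == 1.0

    def test_affine_intensity_invariance(self):
        img, _ = _image(12, seed=7)
        a = detect_cells(img.pixels, PS, PARAMS)
        b = detect_cells(7.3 * img.pixels, PS, PARAMS)
        assert a.total_count == b.total_count
        np.testing.assert_allclose(
            np.sort(a.centroids, axis=0), np.sort(b.centroids, axis=0), atol=1e-9
        )


class TestMatchToTruth:
    def _result(self, pts):
        pts = np.asarray(pts, float).reshape(-1, 2)
        return DetectionResult(
            pts, np.ones(len(pts)), np.array(["single"] * len(pts), object), 0
        )

    def test_identical_sets(self):
        pts = [[1, 1], [5, 5]]
        p, r, rmse = match_to_truth(self._result(pts), np.array(pts, float), 1.0)
        assert (p, r, rmse) == (1.0, 1.0, 0.0)

    def test_one_spurious_detection(self):
        truth = np.array([[1.0, 1.0], [5.0, 5.0]])
        det = self._result([[1, 1], [5, 5], [9, 9]])
        p, r, _ = match_to_truth(det, truth, 0.5)
        assert r == 1.0
        assert p == pytest.approx(2 / 3)

    def test_hand_matching_example(self):
        truth = np.array([[0.0, 0.0], [10.0, 10.0]])
        det = self._result([[0.5, 0.0]])
        p, r, rmse = match_to_truth(det, truth, 1.0)
        assert p == 1.0 and r == 0.5
        assert rmse == pytest.approx(0.5)

    def test_empty_empty_convention(self):
        p, r, rmse = match_to_truth(self._result(np.empty((0, 2))), np.empty((0, 2)), 1.0)
        assert (p, r, rmse) == (1.0, 1.0, 0.0)

    def test_nonpositive_max_dist_rejected(self):
        with pytest.raises(ValueError):
            match_to_truth(self._result([[0, 0]]), np.array([[0.0, 0.0]]), 0.0)
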