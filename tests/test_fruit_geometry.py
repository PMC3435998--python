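"""Contours, MD, focal-form ellipse fitting and the occlusion heuristic."""

import numpy as np
import pytest

from conftest import chord_bitten_ellipse, ellipse_points
from peachvision.fruit_geometry import (
    classify_occlusion,
    estimate_diameter,
    extract_contour,
    fit_ellipse_focal,
    max_pairwise_distance,
    two_stage_fit,
)
from peachvision.synthetic import occlude_fruit, rasterize_ellipse


class TestExtractContour:
    def test_three_by_three_square(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        contour = extract_contour(mask)
        expected = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        assert {tuple(p) for p in contour} == expected

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert extract_contour(mask).tolist() == [[1, 1]]

    def test_border_pixels_count_as_boundary(self):
        mask = np.ones((3, 3), dtype=bool)
        contour = {tuple(p) for p in extract_contour(mask)}
        assert (0, 0) in contour and (2, 2) in contour
        assert (1, 1) not in contour

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            extract_contour(np.zeros((4, 4), dtype=bool))

    def test_matches_four_neighborhood_loop_oracle(self, rng):
        mask = rng.random((30, 30)) > 0.5
        contour = {tuple(p) for p in extract_contour(mask)}
        h, w = mask.shape
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    assert (r, c) not in contour
                    continue
                on_border = r in (0, h - 1) or c in (0, w - 1)
                bg_neighbor = any(
                    not mask[r + dr, c + dc]
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1))
                    if 0 <= r + dr < h and 0 <= c + dc < w
                )
                assert ((r, c) in contour) == (on_border or bg_neighbor)


class TestMaxPairwiseDistance:
    def test_three_four_five(self):
        assert max_pairwise_distance(np.array([[0, 0], [3, 4]])) == 5.0

    def test_unit_square(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        assert max_pairwise_distance(pts) == pytest.approx(np.sqrt(2))

    def test_fewer_than_two_points_is_an_error(self):
        with pytest.raises(ValueError):
            max_pairwise_distance(np.array([[1.0, 1.0]]))

    def test_matches_exhaustive_oracle(self, rng):
        pts = rng.uniform(0, 200, (300, 2))
        brute = max(
            float(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
            for i in range(len(pts)) for j in range(i + 1, len(pts))
        )
        assert max_pairwise_distance(pts) == brute

    def test_hull_shortcut_is_exact(self, rng):
        # > 400 points triggers the convex-hull path
        pts = rng.uniform(0, 500, (600, 2))
        from scipy.spatial.distance import pdist
        assert max_pairwise_distance(pts) == pdist(pts).max()


class TestFitEllipseFocal:
    def test_recovers_known_foci_and_axis(self):
        # foci (+-30, 0) about center (100, 100), a = 50
        a, c = 50.0, 30.0
        b = np.sqrt(a * a - c * c)
        pts = ellipse_points(a, b, n=100)
        fit = fit_ellipse_focal(pts)
        assert fit.major_axis_length == pytest.approx(100.0, abs=1e-3)
        foci = sorted([tuple(fit.focus1), tuple(fit.focus2)])
        assert np.allclose(foci[0], (70.0, 100.0), atol=0.01)
        assert np.allclose(foci[1], (130.0, 100.0), atol=0.01)

    def test_circle_gives_coincident_foci(self):
        pts = ellipse_points(40.0, 40.0, n=100)
        fit = fit_ellipse_focal(pts)
        assert fit.major_axis_length == pytest.approx(80.0, abs=1e-3)
        assert fit.focal_distance < 1e-3

    def test_exact_points_have_negligible_residuals(self, rng):
        pts = ellipse_points(55.0, 42.0, angle=0.6, n=100, rng=rng)
        fit = fit_ellipse_focal(pts)
        assert fit.relative_residuals.max() < 1e-6

    def test_major_axis_never_shorter_than_focal_distance(self, rng):
        for _ in range(5):
            a = rng.uniform(30, 60)
            b = a * rng.uniform(0.72, 0.95)
            pts = ellipse_points(a, b, angle=rng.uniform(0, np.pi), n=80, rng=rng)
            fit = fit_ellipse_focal(pts)
            assert fit.major_axis_length >= fit.focal_distance - 1e-9

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            fit_ellipse_focal(np.zeros((4, 2)))


class TestTwoStageFit:
    def test_exact_ellipse_rejects_nothing(self):
        pts = ellipse_points(50.0, 40.0, angle=0.3, n=100)
        f1, f2, rejected = two_stage_fit(pts)
        assert rejected.size == 0
        assert f2.major_axis_length == f1.major_axis_length
        assert np.array_equal(f2.focus1, f1.focus1)

    def test_chord_bite_is_rejected_and_refit_improves(self, rng):
        pts, is_chord, true_mal = chord_bitten_ellipse(rng)
        f1, f2, rejected = two_stage_fit(pts)
        assert rejected.size > 0
        assert set(rejected) <= set(np.nonzero(is_chord)[0])
        assert (abs(f2.major_axis_length - true_mal)
                < abs(f1.major_axis_length - true_mal))

    def test_scattered_outliers_beyond_threshold_are_rejected(self, rng):
        a, b = 50.0, 40.0
        pts = ellipse_points(a, b, n=95, rng=rng)
        outliers = rng.uniform(20, 180, (5, 2))
        all_pts = np.vstack([pts, outliers])
        f1, f2, rejected = two_stage_fit(all_pts)
        # any outlier farther than 0.15 * 2a from the ellipse has a focal
        # residual of at least that distance, hence exceeds the threshold
        c = np.sqrt(a * a - b * b)
        foci = (np.array([100 + c, 100.0]), np.array([100 - c, 100.0]))
        res = (np.linalg.norm(outliers - foci[0], axis=1)
               + np.linalg.norm(outliers - foci[1], axis=1) - 2 * a)
        far = np.nonzero(np.abs(res) > 0.15 * 2 * a)[0] + 95
        assert set(far) <= set(rejected)

    def test_refit_not_worse_on_retained_points(self, rng):
        pts, _, _ = chord_bitten_ellipse(rng)
        f1, f2, rejected = two_stage_fit(pts)
        keep = np.setdiff1d(np.arange(len(pts)), rejected)

        def robust_cost(fit):
            d1 = np.linalg.norm(pts[keep] - fit.focus1, axis=1)
            d2 = np.linalg.norm(pts[keep] - fit.focus2, axis=1)
            r = d1 + d2 - fit.major_axis_length
            return np.sum(np.arctan(r ** 2))

        assert robust_cost(f2) <= robust_cost(f1) + 1e-9

    def test_fallback_when_rejection_would_leave_too_few(self):
        # 6 points, threshold so small everything would be rejected
        pts = ellipse_points(30.0, 25.0, n=6)
        f1, f2, rejected = two_stage_fit(pts, residual_threshold=1e-15)
        assert rejected.size == 0
        assert f2.major_axis_length == f1.major_axis_length


class TestClassifyOcclusion:
    @pytest.mark.parametrize("f1,f2,expected", [
        (100.0, 100.0, "non_occluded"),
        (100.0, 104.9, "non_occluded"),
        (100.0, 120.0, "occluded_le_33"),
        (100.0, 80.0, "occluded_gt_66"),
    ])
    def test_decision_rule(self, f1, f2, expected):
        assert classify_occlusion(f1, f2) == expected

    def test_nonpositive_inputs_are_errors(self):
        with pytest.raises(ValueError):
            classify_occlusion(0.0, 100.0)
        with pytest.raises(ValueError):
            classify_occlusion(100.0, -5.0)


class TestEstimateDiameter:
    def test_unoccluded_ellipse_mask(self):
        mask, _ = rasterize_ellipse((160, 160), (80, 80), 40.0, 30.0, 0.5)
        est = estimate_diameter(mask)
        assert est.occlusion_class == "non_occluded"
        assert est.md == pytest.approx(80.0, abs=2.0)
        assert est.mal_f1 == pytest.approx(80.0, abs=2.0)
        assert est.mal_f2 == pytest.approx(80.0, abs=2.0)
        assert est.recommended_diameter is not None

    def test_rasterized_disk_closed_form(self):
        r = 25.0
        mask, _ = rasterize_ellipse((120, 120), (60, 60), r, r, 0.0)
        est = estimate_diameter(mask)
        assert est.md == pytest.approx(2 * r, abs=2.0)
        assert est.mal_f1 == pytest.approx(2 * r, abs=2.0)

    def test_tiny_mask_is_an_error(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True  # 4 contour pixels only
        with pytest.raises(ValueError):
            estimate_diameter(mask)

    def test_md_shrinks_under_occlusion(self, rng):
        # occluded contour is a subset of the fruit, so MD cannot grow
        for seed in range(5):
            local = np.random.default_rng(seed)
            mask, _ = rasterize_ellipse((160, 160), (80, 80), 38.0, 29.0, 1.0)
            visible, _, _ = occlude_fruit(mask, 0.3, local)
            md_full = max_pairwise_distance(extract_contour(mask).astype(float))
            md_occ = max_pairwise_distance(extract_contour(visible).astype(float))
            assert md_occ <= md_full + 1e-9
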