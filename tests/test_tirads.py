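"""ACR TI-RADS extraction, scoring, level mapping and rater comparison."""

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from thyroscan import phantom
from thyroscan.tirads import (
    GlandStats,
    PixelBands,
    TiradsConfig,
    classify_nodule_pixels,
    compare_reports,
    compare_rating_table,
    composition_score,
    echogenicity_score,
    ellipse_fit_iou,
    foci_score,
    gland_histogram_stats,
    load_bundled_ratings,
    margin_score,
    margin_statistic,
    recommendation,
    score_nodule,
    shape_score,
    total_and_level,
)

from conftest import render_nodule


class TestGlandHistogramStats:
    def test_constant_gland(self):
        img = np.full((12, 12), 100, np.uint8)
        stats = gland_histogram_stats(img, np.ones((12, 12), bool))
        assert stats.mu == 100.0 and stats.sigma == 0.0

    def test_bimodal_modes_only(self):
        """Two equal modes at 80 and 120 with a sub-average valley keep only
        the modal bins: mu = 100, sigma = 20."""
        img = np.zeros((20, 20), np.uint8)
        img[:10] = 80
        img[10:] = 120
        stats = gland_histogram_stats(img, np.ones((20, 20), bool), smoothing_window=3)
        assert stats.mu == pytest.approx(100.0)
        assert stats.sigma == pytest.approx(20.0)

    def test_window_one_keeps_histogram(self):
        img = np.full((8, 8), 42, np.uint8)
        stats = gland_histogram_stats(img, np.ones((8, 8), bool), smoothing_window=1)
        assert stats.smoothed_hist[42] == 64
        assert stats.smoothed_hist.sum() == pytest.approx(64)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            gland_histogram_stats(np.zeros((4, 4), np.uint8), np.zeros((4, 4), bool))


class TestPixelBands:
    @staticmethod
    def stats(mu=100.0, sigma=10.0):
        return GlandStats(np.zeros(256), 0.0, mu, sigma)

    def test_fractions_sum_to_one(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        mask = np.ones((16, 16), bool)
        fractions = classify_nodule_pixels(img, mask, self.stats())
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pixels_at_gland_mean_are_iso(self):
        img = np.full((8, 8), 100, np.uint8)
        fractions = classify_nodule_pixels(img, np.ones((8, 8), bool), self.stats())
        assert fractions["iso"] == 1.0

    def test_cystic_fraction_matches_counting_oracle(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        mask = np.ones((16, 16), bool)
        stats = self.stats(120.0, 15.0)
        fractions = classify_nodule_pixels(img, mask, stats)
        threshold = 120.0 - 2.5 * 15.0
        expected = np.mean([v < threshold for v in img.ravel()])
        assert fractions["cystic"] == pytest.approx(expected)

    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            PixelBands(cystic_hi=-1.0, hypo_hi=-2.0)


class TestComponentScores:
    def test_composition_thresholds(self):
        assert composition_score({"cystic": 0.02}) == 2
        assert composition_score({"cystic": 0.4}) == 1
        assert composition_score({"cystic": 1.0}) == 0

    def test_echogenicity_mapping(self):
        base = {"cystic": 0.0, "hypo": 0.0, "iso": 0.0, "hyper": 0.0, "calcification": 0.0}
        assert echogenicity_score({**base, "hypo": 0.8, "iso": 0.2}) == 2
        assert echogenicity_score({**base, "iso": 0.9, "hypo": 0.1}) == 1
        assert echogenicity_score({**base, "hyper": 0.7, "iso": 0.3}) == 1
        assert echogenicity_score({**base, "cystic": 0.95, "iso": 0.05}) == 0

    def test_very_hypo_requires_configured_reference(self):
        base = {"cystic": 0.0, "hypo": 0.9, "iso": 0.1, "hyper": 0.0, "calcification": 0.0}
        cfg = TiradsConfig(very_hypo_reference=60.0)
        assert echogenicity_score(base, nodule_mean=40.0, config=cfg) == 3
        assert echogenicity_score(base, nodule_mean=40.0) == 2  # disabled by default

    def test_shape_taller_than_wide(self):
        tall = np.zeros((20, 20), bool)
        tall[2:14, 5:15] = True  # 12 deep x 10 wide
        assert shape_score(tall)[0] == 3
        wide = tall.T.copy()
        assert shape_score(wide)[0] == 0
        square = np.zeros((10, 10), bool)
        square[2:8, 2:8] = True
        assert shape_score(square)[0] == 0  # exact 1.0 scores 0


class TestMarginAndEllipse:
    def test_rasterized_ellipse_has_high_iou(self):
        mask = np.zeros((48, 48), bool)
        rr, cc = draw_ellipse(24, 24, 10, 16, rotation=0.4)
        mask[rr, cc] = True
        assert ellipse_fit_iou(mask) >= 0.95

    def test_plus_sign_fits_worse_than_true_ellipse(self):
        plus = np.zeros((40, 40), bool)
        plus[8:32, 17:23] = True
        plus[17:23, 8:32] = True
        ellipse = np.zeros((40, 40), bool)
        rr, cc = draw_ellipse(20, 20, 9, 9)
        ellipse[rr, cc] = True
        assert ellipse_fit_iou(plus) < ellipse_fit_iou(ellipse)

    def test_iou_in_unit_interval(self, rng):
        mask = np.zeros((30, 30), bool)
        mask[rng.random((30, 30)) > 0.5] = True
        mask[10:20, 10:20] = True
        iou = ellipse_fit_iou(mask)
        assert 0.0 <= iou <= 1.0

    def test_smooth_high_contrast_ellipse_scores_zero(self):
        img = np.full((48, 48), 120, np.uint8)
        mask = np.zeros((48, 48), bool)
        rr, cc = draw_ellipse(24, 24, 9, 14)
        mask[rr, cc] = True
        img[mask] = 60
        points, info = margin_score(img, mask)
        assert points == 0
        assert info["ellipse_iou"] >= 0.95

    def test_star_shaped_boundary_scores_irregular(self):
        yy, xx = np.mgrid[0:64, 0:64]
        phi = np.arctan2(yy - 32.0, xx - 32.0)
        r = np.hypot(yy - 32.0, xx - 32.0)
        mask = r < 18.0 * (1.0 + 0.4 * np.cos(5 * phi))
        img = np.full((64, 64), 120, np.uint8)
        img[mask] = 60
        points, info = margin_score(img, mask)
        assert points == 2
        assert info["ellipse_iou"] < 0.85

    def test_margin_statistic_matches_normal_sampling_oracle(self):
        """On a small two-level case the statistic equals the mean over
        boundary pixels of the 11-sample std computed explicitly."""
        img = np.full((32, 32), 200, np.uint8)
        mask = np.zeros((32, 32), bool)
        mask[10:22, 10:22] = True
        img[mask] = 40
        from scipy.ndimage import distance_transform_edt
        from thyroscan.losses import mask_boundary

        signed = distance_transform_edt(~mask) - distance_transform_edt(mask)
        gy, gx = np.gradient(signed.astype(float))
        stds = []
        for y, x in zip(*np.nonzero(mask_boundary(mask))):
            n = np.hypot(gy[y, x], gx[y, x])
            if n == 0:
                continue
            ny, nx = gy[y, x] / n, gx[y, x] / n
            samples = []
            for k in range(-5, 6):
                rr = min(max(int(round(y + k * ny)), 0), 31)
                cc = min(max(int(round(x + k * nx)), 0), 31)
                samples.append(float(img[rr, cc]))
            stds.append(np.std(samples))
        assert margin_statistic(img, mask) == pytest.approx(np.mean(stds), abs=1e-9)


class TestFoci:
    @staticmethod
    def stats():
        return GlandStats(np.zeros(256), 0.0, 100.0, 10.0)

    def test_no_calcification_band_pixels_scores_zero(self):
        img = np.full((20, 20), 100, np.uint8)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        points, info = foci_score(img, mask, self.stats())
        assert points == 0 and info["pattern"] == "none"

    def test_generated_punctate_pattern_scores_three(self):
        spec = phantom.default_nodule(width_mm=9.0, depth_mm=7.0, foci_pattern="punctate")
        frame = render_nodule(spec, seed=21)
        sc = score_nodule(frame.image, frame.gland_mask, frame.nodule_masks[1], 0.5)
        assert sc.foci == 3

    def test_generated_peripheral_rim_scores_two(self):
        spec = phantom.default_nodule(width_mm=9.0, depth_mm=7.0, foci_pattern="peripheral")
        frame = render_nodule(spec, seed=22)
        sc = score_nodule(frame.image, frame.gland_mask, frame.nodule_masks[1], 0.5)
        assert sc.foci == 2

    def test_generated_macro_focus_scores_one(self):
        spec = phantom.default_nodule(width_mm=9.0, depth_mm=7.0, foci_pattern="macro")
        frame = render_nodule(spec, seed=23)
        sc = score_nodule(frame.image, frame.gland_mask, frame.nodule_masks[1], 0.5)
        assert sc.foci == 1


class TestTotalsLevelsRecommendations:
    def test_worked_solid_hypo_taller_nodule(self):
        total, level, name = total_and_level((2, 2, 0, 3, 0))
        assert (total, level) == (7, 5)
        assert name == "highly suspicious"

    def test_worked_mixed_hypo_nodule(self):
        total, level, name = total_and_level((1, 2, 0, 0, 0))
        assert (total, level) == (3, 3)
        assert name == "mildly suspicious"

    def test_all_zero_is_tr1(self):
        assert total_and_level((0, 0, 0, 0, 0))[:2] == (0, 1)

    @pytest.mark.parametrize(
        "points,level",
        [((0, 1, 0, 0, 0), 1), ((1, 1, 0, 0, 0), 2), ((2, 2, 0, 0, 0), 4),
         ((2, 2, 2, 3, 3), 5)],
    )
    def test_level_mapping_table(self, points, level):
        assert total_and_level(points)[1] == level

    def test_component_range_enforced(self):
        with pytest.raises(ValueError):
            total_and_level((3, 0, 0, 0, 0))

    def test_recommendations_from_published_rows(self):
        assert recommendation(3, 18.6) == "follow-up"
        assert recommendation(4, 12.4) == "follow-up"
        assert recommendation(1, 50.0) == "no FNA"
        assert recommendation(5, 10.0) == "FNA"
        assert recommendation(5, 6.0) == "follow-up"
        assert recommendation(3, 26.0) == "FNA"

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            recommendation(3, 0.0)


class TestComparison:
    def test_identical_tables_all_zero(self):
        report = compare_reports([3, 4, 5], [3, 4, 5])
        assert report.differences == [0, 0, 0]
        assert report.agreement_count == 3

    def test_symmetric(self):
        a, b = [1, 5, 2], [4, 5, 0]
        assert compare_reports(a, b).histogram == compare_reports(b, a).histogram

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_reports([1], [1, 2])

    def test_bundled_table_difference_histogram(self):
        """Totaling the bundled 24-nodule two-rater table yields 8 nodules
        at difference 1 and 4 at difference 2."""
        df = load_bundled_ratings()
        assert len(df) == 48
        report = compare_rating_table(df)
        assert report.histogram[1] == 8
        assert report.histogram[2] == 4


class TestFeatureRecovery:
    def test_generated_classes_recovered(self):
        """Composition, echogenicity and shape points recover the generating
        class on a seeded suite of rendered nodules."""
        comp_classes = [("cystic", 0.95, 0), ("mixed", 0.45, 1), ("solid", 0.02, 2)]
        echo_classes = [("hypo", -40.0, 2), ("iso", 0.0, 1), ("hyper", 40.0, 2 - 1)]
        hits, n = 0, 0
        for i in range(18):
            _, cf, cexp = comp_classes[i % 3]
            _, eo, eexp = echo_classes[(i // 3) % 3]
            taller = (i // 9) % 2 == 0
            w, d = (6.0, 8.0) if taller else (9.0, 6.0)
            spec = phantom.default_nodule(
                width_mm=w, depth_mm=d, cystic_fraction=cf, echo_offset=eo
            )
            frame = render_nodule(spec, seed=700 + i)
            sc = score_nodule(frame.image, frame.gland_mask, frame.nodule_masks[1], 0.5)
            n += 2 + (cf < 0.1)
            hits += sc.composition == cexp
            hits += sc.shape == (3 if d > w else 0)
            if cf < 0.1:
                hits += sc.echogenicity == eexp
        assert hits / n >= 0.9
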