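"""Segmentation loss suite: oracles, invariants and the demo trainer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from thyroscan import losses
from thyroscan.losses import (
    LossConfig,
    SegSample,
    distance_loss,
    distance_weight,
    feature_loss,
    gaussian_feature_weight,
    gland_intensity_stats,
    iou_loss,
    iso_hybrid_loss,
    mask_boundary,
    soft_iou,
)


def brute_force_distance_weight(mask: np.ndarray) -> np.ndarray:
    """Exhaustive O(N^2) nearest-boundary scan."""
    mask = mask.astype(bool)
    h, w = mask.shape
    boundary = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    boundary.append((r, c))
                    break
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                continue
            out[r, c] = min(
                np.sqrt((r - br) ** 2 + (c - bc) ** 2) for br, bc in boundary
            )
    return out


class TestGlandStats:
    def test_constant_gland(self):
        img = np.full((8, 8), 100.0)
        mask = np.ones((8, 8), bool)
        assert gland_intensity_stats(img, mask) == (100.0, 0.0)

    def test_two_pixel_hand_computation(self):
        img = np.array([[80.0, 120.0]])
        assert gland_intensity_stats(img, np.ones((1, 2), bool)) == (100.0, 20.0)

    def test_full_mask_equals_global_stats(self, rng):
        img = rng.integers(0, 255, (16, 16)).astype(float)
        avg, std = gland_intensity_stats(img, np.ones_like(img, bool))
        assert avg == pytest.approx(img.mean())
        assert std == pytest.approx(img.std())

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            gland_intensity_stats(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestGaussianFeatureWeight:
    def test_zero_at_gland_mean(self):
        assert gaussian_feature_weight(np.array([[100.0]]), 100.0, 15.0)[0, 0] == 0.0

    def test_one_sigma_closed_form(self):
        w = gaussian_feature_weight(np.array([[115.0, 85.0]]), 100.0, 15.0)
        expected = 1.0 - np.exp(-0.5)
        assert np.allclose(w, expected)
        assert expected == pytest.approx(0.39347, abs=1e-5)

    def test_symmetric_and_monotone(self):
        devs = np.array([[0.0, 5.0, 10.0, 20.0, 80.0]])
        up = gaussian_feature_weight(100.0 + devs, 100.0, 10.0)[0]
        down = gaussian_feature_weight(100.0 - devs, 100.0, 10.0)[0]
        assert np.allclose(up, down)
        assert np.all(np.diff(up) > 0)
        assert up[-1] > 0.999

    def test_zero_std_limit_convention(self):
        w = gaussian_feature_weight(np.array([[100.0, 101.0]]), 100.0, 0.0)
        assert w.tolist() == [[0.0, 1.0]]


class TestSoftIouLosses:
    def test_perfect_binary_prediction_zero_loss(self):
        gt = np.zeros((4, 4))
        gt[1:3, 1:3] = 1.0
        assert iou_loss(gt, gt) == 0.0
        assert feature_loss(gt, gt, np.ones_like(gt)) == 0.0

    def test_disjoint_prediction_loss_one(self):
        gt = np.zeros((4, 4))
        gt[0, 0] = 1.0
        pred = np.zeros((4, 4))
        pred[3, 3] = 1.0
        assert iou_loss(pred, gt) == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap_hand_computation(self):
        # |intersection| = 1, |union| = 3 on a 2x2 grid
        gt = np.array([[1.0, 1.0], [0.0, 0.0]])
        pred = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert iou_loss(pred, gt) == pytest.approx(2.0 / 3.0, abs=1e-5)

    def test_worked_4x4_weighted_soft_iou(self):
        """Hand-computed sum-min over sum-max with a stated weight map."""
        gt = np.zeros((4, 4))
        gt[1:3, 1:3] = 1.0
        pred = np.full((4, 4), 0.5)
        w = np.ones((4, 4))
        w[1:3, 1:3] = 0.8
        weighted = w * pred  # 0.4 inside gt, 0.5 elsewhere
        inter = 0.4 * 4  # min(0.4, 1) inside gt
        union = 1.0 * 4 + 0.5 * 12  # max inside + max outside
        expected = 1.0 - inter / union
        assert feature_loss(pred, gt, w) == pytest.approx(expected, abs=1e-5)
        assert soft_iou(weighted, gt) == pytest.approx(inter / union, abs=1e-5)

    def test_feature_loss_reduces_to_iou_loss_with_unit_weight(self, rng):
        gt = (rng.random((8, 8)) > 0.6).astype(float)
        pred = rng.random((8, 8))
        assert feature_loss(pred, gt, np.ones_like(gt)) == pytest.approx(
            iou_loss(pred, gt)
        )

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            iou_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestDistanceWeight:
    def test_zero_inside_gland(self):
        mask = np.zeros((6, 6), bool)
        mask[2:5, 2:5] = True
        w = distance_weight(mask)
        assert np.all(w[mask] == 0.0)

    def test_four_adjacent_pixel_distance_one(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        assert distance_weight(mask)[1, 2] == 1.0
        assert distance_weight(mask)[2, 4] == 1.0

    def test_matches_exhaustive_oracle_on_12x12(self, rng):
        mask = np.zeros((12, 12), bool)
        mask[3:8, 2:7] = True
        mask[6:10, 6:10] = True
        assert np.array_equal(distance_weight(mask), brute_force_distance_weight(mask))

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((12, 12)) > 0.6
            if not mask.any():
                continue
            assert np.array_equal(
                distance_weight(mask), brute_force_distance_weight(mask)
            )

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            distance_weight(np.zeros((4, 4), bool))

    def test_boundary_is_4_adjacency(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        b = mask_boundary(mask)
        assert b[1, 1] and b[1, 2] and not b[2, 2]


class TestDistanceLoss:
    def test_prediction_inside_gland_is_zero(self):
        gland = np.zeros((8, 8), bool)
        gland[2:6, 2:6] = True
        pred = np.zeros((8, 8))
        pred[3:5, 3:5] = 1.0
        assert distance_loss(pred, distance_weight(gland)) == 0.0

    def test_single_pixel_at_distance_five(self):
        gland = np.zeros((8, 16), bool)
        gland[:, :8] = True
        pred = np.zeros((8, 16))
        pred[4, 12] = 1.0  # five columns right of the boundary column 7
        w = distance_weight(gland)
        assert w[4, 12] == 5.0
        assert distance_loss(pred, w, "mean-over-predicted") == pytest.approx(5.0, rel=1e-5)

    def test_zero_prediction_is_zero(self):
        gland = np.ones((4, 4), bool)
        assert distance_loss(np.zeros((4, 4)), distance_weight(gland)) == 0.0

    def test_raw_sum_mode(self):
        gland = np.zeros((4, 8), bool)
        gland[:, :4] = True
        pred = np.zeros((4, 8))
        pred[0, 5] = 1.0
        pred[1, 5] = 1.0
        assert distance_loss(pred, distance_weight(gland), "raw-sum") == pytest.approx(4.0)


class TestIsoHybrid:
    @staticmethod
    def sample():
        img = np.full((8, 8), 90, np.uint8)
        img[2:6, 2:6] = 120
        gt = np.zeros((8, 8))
        gt[3:5, 3:5] = 1.0
        gland = np.zeros((8, 8))
        gland[2:6, 2:6] = 1.0
        pred = np.zeros((8, 8))
        pred[3:5, 3:6] = 1.0  # one column spills outside gt but inside gland
        return SegSample(image=img, gt=gt, n_pred=pred, g_pred=gland)

    def test_alpha_beta_zero_equals_iou_loss(self):
        s = self.sample()
        assert iso_hybrid_loss(s, LossConfig(alpha=0.0, beta=0.0)) == pytest.approx(
            iou_loss(s.n_pred, s.gt)
        )

    def test_affine_in_beta(self):
        s = self.sample()
        base = iso_hybrid_loss(s, LossConfig(alpha=0.0, beta=0.0))
        l1 = iso_hybrid_loss(s, LossConfig(alpha=0.0, beta=1.0))
        l2 = iso_hybrid_loss(s, LossConfig(alpha=0.0, beta=2.0))
        assert l2 - base == pytest.approx(2.0 * (l1 - base), abs=1e-9)

    def test_worked_sample_component_sum(self):
        s = self.sample()
        cfg = LossConfig(alpha=0.7, beta=0.3)
        parts = losses.iso_hybrid_components(s, cfg)
        expected = parts["iou"] + 0.7 * parts["feature"] + 0.3 * parts["distance"]
        assert iso_hybrid_loss(s, cfg) == pytest.approx(expected, abs=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            LossConfig(dist_normalization="bogus")

    @settings(deadline=None, max_examples=25)
    @given(
        pred=hnp.arrays(float, (6, 6), elements=st.floats(0, 1)),
        gt_bits=hnp.arrays(bool, (6, 6)),
    )
    def test_losses_bounded(self, pred, gt_bits):
        gt = gt_bits.astype(float)
        assert 0.0 <= iou_loss(pred, gt) <= 1.0
        w = gaussian_feature_weight(pred * 255, 100.0, 20.0)
        assert 0.0 <= feature_loss(pred, gt, w) <= 1.0
        gland = np.zeros((6, 6), bool)
        gland[1:4, 1:4] = True
        assert distance_loss(pred, distance_weight(gland)) >= 0.0


@pytest.fixture(scope="module")
def dataset():
    return losses.make_demo_dataset(10, seed=3)


class TestDemoTrainer:
    def test_smoke_one_epoch_finite(self, dataset):
        model, val_iou, curve = losses.train_demo_segmenter(
            dataset[:8], seed=0, epochs=1
        )
        assert np.isfinite(curve).all()
        assert 0.0 <= val_iou <= 1.0

    def test_loss_decreases_over_epochs(self, dataset):
        _, _, curve = losses.train_demo_segmenter(
            dataset, seed=4, epochs=10, lr=2.0
        )
        assert curve[-1] < curve[0]

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            losses.train_demo_segmenter([], seed=0)

    def test_deterministic_per_seed(self, dataset):
        m1, v1, c1 = losses.train_demo_segmenter(dataset[:6], seed=9, epochs=2)
        m2, v2, c2 = losses.train_demo_segmenter(dataset[:6], seed=9, epochs=2)
        assert np.array_equal(m1.weights, m2.weights)
        assert v1 == v2 and c1 == c2
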