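import math

import numpy as np
import pytest

from conftest import random_detection_set
from gaze_priority.detections import (
    BoundingBox,
    DetectionParams,
    DetectionSet,
    ObjectProposal,
)
from gaze_priority.priority_maps import (
    GaussianSpec,
    PriorityMap,
    center_bias_map,
    gaussian_blob,
    histogram_match,
    label_entropy_map,
    load_saliency,
    minmax_normalize,
    pixelwise_uncertainty_map,
    save_map,
    self_information,
    smoothing_kernel,
    standin_saliency,
    target_map_ta,
    target_map_tp,
    uncertainty_map,
    unique_object_probability,
)
from oracles import (
    box_count_oracle,
    center_bias_oracle,
    entropy_oracle,
    gauss,
    smooth_oracle,
    target_map_oracle,
    uncertainty_oracle,
)

PARAMS = DetectionParams()


def _single(box, scores, size=(48, 48)):
    return DetectionSet("im", size, [ObjectProposal(box, scores)])


class TestGaussianBlob:
    def test_argmax_at_center(self):
        m = gaussian_blob(GaussianSpec((5.0, 5.0), 2.0), (11, 11))
        assert np.unravel_index(m.values.argmax(), m.shape) == (5, 5)

    def test_one_sigma_falloff(self):
        m = gaussian_blob(GaussianSpec((5.0, 5.0), 2.0), (11, 11))
        assert m.values[5, 5] / m.values[5, 7] == pytest.approx(math.exp(0.5))

    def test_pointwise_closed_form(self):
        m = gaussian_blob(GaussianSpec((3.0, 2.0), 2.0), (7, 7))
        for i in range(7):
            for j in range(7):
                assert m.values[i, j] == pytest.approx(
                    gauss(j, i, 3.0, 2.0, 2.0, 2.0), rel=1e-12
                )

    def test_truncated_support_zero_outside(self):
        m = gaussian_blob(GaussianSpec((5.0, 5.0), 2.0, support=5), (11, 11))
        assert m.values[5, 5] > 0
        assert m.values[5, 0] == 0.0
        assert m.values[0, 5] == 0.0

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            GaussianSpec((0, 0), 0.0)


class TestUniqueObjectProbability:
    def test_worked_normalization(self):
        # four proposal boxes with competing counts 3, 2, 1, 4
        assert unique_object_probability([3, 2, 1, 4]) == pytest.approx(
            [0.70, 0.80, 0.90, 0.60], abs=1e-12
        )

    def test_two_symmetric_boxes(self):
        assert unique_object_probability([1, 1]) == pytest.approx([0.5, 0.5])

    def test_five_equal_counts(self):
        assert unique_object_probability([5] * 5) == pytest.approx([0.8] * 5)

    def test_sums_to_boxes_minus_one(self, rng):
        for _ in range(20):
            f = rng.integers(1, 9, size=int(rng.integers(2, 10)))
            p = unique_object_probability(f)
            assert p.sum() == pytest.approx(len(f) - 1, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            unique_object_probability([])
        with pytest.raises(ValueError):
            unique_object_probability([0, 2])


class TestSelfInformation:
    def test_certainty_is_zero(self):
        assert self_information(1.0) == 0.0

    @pytest.mark.parametrize("p, si", [(0.60, 0.222), (0.70, 0.155)])
    def test_base10_values(self, p, si):
        assert self_information(p) == pytest.approx(si, abs=5e-4)

    def test_strictly_decreasing(self):
        ps = np.linspace(0.05, 1.0, 40)
        si = self_information(ps)
        assert np.all(np.diff(si) < 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            self_information(0.0)


class TestUncertaintyMap:
    def test_single_proposal_peak_weight_one(self):
        # odd box side so the continuous center falls on a pixel center
        box = BoundingBox(10, 10, 17, 17)
        m = uncertainty_map(_single(box, {"cup": 0.6, "bowl": 0.2}), PARAMS)
        cx, cy = box.center
        # f_b / max f_b = 1 regardless of the count, so peak value is 1
        assert m.values.max() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(m.values.argmax(), m.shape) == (cy, cx)

    def test_two_distant_proposals_weight_ratio(self):
        ds = DetectionSet(
            "im", (64, 128),
            [
                ObjectProposal(
                    BoundingBox(8, 24, 16, 16),
                    {"cup": 0.5, "bowl": 0.2, "fork": 0.1, "car": 0.05},
                ),
                ObjectProposal(
                    BoundingBox(100, 24, 16, 16), {"clock": 0.5, "bottle": 0.2}
                ),
            ],
        )
        m = uncertainty_map(ds, PARAMS)
        peak1 = m.values[31, 15]  # center of box 1 (f=4 -> weight 1.0)
        peak2 = m.values[31, 107]  # center of box 2 (f=2 -> weight 0.5)
        assert peak1 / peak2 == pytest.approx(2.0, rel=1e-6)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            ds = random_detection_set(rng, image_size=(32, 32), n_proposals=4)
            m = uncertainty_map(ds, PARAMS)
            expected = uncertainty_oracle(ds, PARAMS.th_conf, PARAMS.th_nms)
            np.testing.assert_allclose(m.values, expected, rtol=1e-9, atol=1e-12)

    def test_proposal_order_invariance(self, rng):
        ds = random_detection_set(rng, image_size=(32, 32), n_proposals=5)
        perm = DetectionSet(
            ds.image_id, ds.image_size,
            [ds.proposals[i] for i in rng.permutation(len(ds))],
        )
        np.testing.assert_allclose(
            uncertainty_map(ds, PARAMS).values,
            uncertainty_map(perm, PARAMS).values,
            rtol=1e-9,
        )

    def test_zero_proposals_zero_map(self, caplog):
        ds = DetectionSet("im", (16, 16), [])
        with caplog.at_level("WARNING"):
            m = uncertainty_map(ds, PARAMS)
        assert not m.values.any()
        assert "no surviving proposals" in caplog.text


class TestLabelEntropyMap:
    def test_single_category_zero_weight(self):
        m = label_entropy_map(_single(BoundingBox(10, 10, 16, 16), {"cup": 0.9}), PARAMS)
        assert not m.values.any()

    @pytest.mark.parametrize("k", [2, 4])
    def test_uniform_confidences_give_log10_k(self, k):
        cats = ["cup", "bowl", "fork", "clock"][:k]
        m = label_entropy_map(
            _single(BoundingBox(16, 16, 17, 17), {c: 0.2 for c in cats}), PARAMS
        )
        assert m.values.max() == pytest.approx(math.log10(k), rel=1e-9)

    def test_renormalized_entropy_example(self):
        m = label_entropy_map(
            _single(BoundingBox(16, 16, 17, 17), {"cup": 0.5, "bowl": 0.03}), PARAMS
        )
        p = np.array([0.5, 0.03]) / 0.53
        expected = -(p * np.log10(p)).sum()
        assert m.values.max() == pytest.approx(expected, rel=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            ds = random_detection_set(rng, image_size=(32, 32), n_proposals=4)
            m = label_entropy_map(ds, PARAMS)
            expected = entropy_oracle(ds, PARAMS.th_conf, PARAMS.th_nms)
            np.testing.assert_allclose(m.values, expected, rtol=1e-9, atol=1e-12)


class TestPixelwiseUncertaintyMap:
    def test_no_proposals_zero(self):
        m = pixelwise_uncertainty_map(DetectionSet("im", (16, 16), []), PARAMS)
        assert not m.values.any()

    def test_one_box_unsmoothed_is_indicator(self):
        ds = _single(BoundingBox(4, 6, 8, 5), {"cup": 0.5}, size=(24, 24))
        m = pixelwise_uncertainty_map(ds, PARAMS, smooth=False)
        expected = np.zeros((24, 24))
        expected[6:11, 4:12] = 1.0
        np.testing.assert_array_equal(m.values, expected)

    def test_overlap_counts_brute_force(self):
        ds = DetectionSet(
            "im", (32, 32),
            [
                ObjectProposal(BoundingBox(4, 4, 16, 16), {"cup": 0.5}),
                ObjectProposal(BoundingBox(10, 10, 16, 16), {"bowl": 0.5}),
                ObjectProposal(BoundingBox(14, 6, 12, 18), {"fork": 0.5}),
            ],
        )
        m = pixelwise_uncertainty_map(ds, PARAMS, smooth=False)
        np.testing.assert_array_equal(m.values, box_count_oracle(ds, PARAMS.th_conf))
        assert m.values.max() == 3  # triple-overlap region exists

    def test_smoothed_matches_direct_convolution(self, rng):
        ds = random_detection_set(rng, image_size=(32, 32), n_proposals=4)
        m = pixelwise_uncertainty_map(ds, PARAMS)
        counts = box_count_oracle(ds, PARAMS.th_conf)
        kernel = smoothing_kernel(int(round(32 / 4)))
        np.testing.assert_allclose(
            m.values, smooth_oracle(counts, kernel), rtol=1e-9, atol=1e-12
        )


class TestCenterBiasMap:
    def test_argmax_at_image_center(self):
        m = center_bias_map((11, 11), 3.0)
        assert np.unravel_index(m.values.argmax(), m.shape) == (5, 5)

    def test_flip_symmetry(self):
        m = center_bias_map((12, 18), 4.0).values
        np.testing.assert_allclose(m, m[::-1, :], rtol=1e-12)
        np.testing.assert_allclose(m, m[:, ::-1], rtol=1e-12)

    def test_closed_form_with_amplitude(self):
        m = center_bias_map((11, 11), 3.0)
        np.testing.assert_allclose(
            m.values, center_bias_oracle((11, 11), 3.0), rtol=1e-12
        )

    def test_default_sigma_is_third_of_height(self):
        assert center_bias_map((30, 40)).meta["sigma_c"] == pytest.approx(10.0)


class TestTargetMaps:
    def test_tp_argmax_at_qualifying_box_center(self):
        ds = _single(BoundingBox(10, 20, 12, 14), {"cup": 0.95}, size=(48, 64))
        m = target_map_tp(ds, "cup")
        i, j = np.unravel_index(m.values.argmax(), m.shape)
        cx, cy = ds.proposals[0].box.center
        assert abs(i - cy) <= 1 and abs(j - cx) <= 1

    def test_tp_no_qualifying_box_zero_with_warning(self, caplog):
        ds = _single(BoundingBox(10, 20, 12, 14), {"cup": 0.5}, size=(48, 64))
        with caplog.at_level("WARNING"):
            m = target_map_tp(ds, "cup")
        assert not m.values.any()
        assert "target map is zero" in caplog.text

    def test_unknown_category_raises(self):
        ds = _single(BoundingBox(10, 20, 12, 14), {"cup": 0.95})
        with pytest.raises(ValueError, match="unknown target category"):
            target_map_tp(ds, "zebra")

    def test_square_box_of_image_height_is_unresampled_gaussian(self):
        h = 32
        ds = _single(BoundingBox(0, 0, h, h), {"cup": 0.95}, size=(h, h))
        m = target_map_tp(ds, "cup")
        c = (h - 1) / 2
        direct = gaussian_blob(GaussianSpec((c, c), h / 4.0), (h, h)).values
        np.testing.assert_allclose(m.values, direct, rtol=1e-9, atol=1e-12)

    def test_ta_zero_when_no_score_above_floor(self, caplog):
        ds = _single(BoundingBox(4, 4, 10, 10), {"cup": 0.01, "bowl": 0.5})
        with caplog.at_level("WARNING"):
            m = target_map_ta(ds, "cup")
        assert not m.values.any()

    def test_ta_single_box_equals_tp(self):
        ds = _single(BoundingBox(8, 10, 14, 12), {"cup": 0.95}, size=(48, 64))
        np.testing.assert_array_equal(
            target_map_ta(ds, "cup").values, target_map_tp(ds, "cup").values
        )

    def test_ta_additive_over_boxes(self):
        boxes = [
            BoundingBox(2, 2, 10, 12),
            BoundingBox(30, 6, 14, 10),
            BoundingBox(12, 30, 12, 12),
        ]
        size = (48, 64)
        full = DetectionSet(
            "im", size, [ObjectProposal(b, {"cup": 0.4}) for b in boxes]
        )
        total = target_map_ta(full, "cup").values
        parts = sum(
            target_map_ta(_single(b, {"cup": 0.4}, size), "cup").values
            for b in boxes
        )
        np.testing.assert_allclose(total, parts, rtol=1e-9, atol=1e-12)

    def test_matches_bilinear_oracle(self, rng):
        for _ in range(4):
            ds = random_detection_set(rng, image_size=(32, 48), n_proposals=3)
            category = next(iter(ds.proposals[0].scores))
            m = target_map_ta(ds, category, conf=0.02)
            expected = target_map_oracle(ds, category, 0.02)
            np.testing.assert_allclose(m.values, expected, rtol=1e-9, atol=1e-12)


class TestPostProcessing:
    def test_minmax_example(self):
        m = PriorityMap(np.array([[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(
            minmax_normalize(m).values, [[0.0, 0.5, 1.0]]
        )

    def test_minmax_idempotent(self, rng):
        m = PriorityMap(rng.uniform(0, 1, (8, 8)))
        once = minmax_normalize(m)
        np.testing.assert_allclose(minmax_normalize(once).values, once.values)

    def test_minmax_preserves_order_statistics(self, rng):
        v = rng.uniform(2, 9, (10, 10))
        out = minmax_normalize(PriorityMap(v)).values
        assert out.min() == 0.0 and out.max() == 1.0
        np.testing.assert_array_equal(
            np.argsort(v.ravel()), np.argsort(out.ravel())
        )

    def test_minmax_constant_warns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = minmax_normalize(PriorityMap(np.full((4, 4), 3.0)))
        assert not out.values.any()
        assert "constant map" in caplog.text

    def test_histmatch_identity_rank_equivalent(self, rng):
        v = rng.uniform(0, 1, (16, 16))
        m = PriorityMap(v)
        out = histogram_match(m, m)
        np.testing.assert_array_equal(
            np.argsort(v.ravel()), np.argsort(out.values.ravel())
        )

    def test_histmatch_constant_reference(self, rng):
        m = PriorityMap(rng.uniform(0, 1, (8, 8)))
        ref = PriorityMap(np.full((8, 8), 0.7))
        np.testing.assert_allclose(histogram_match(m, ref).values, 0.7)

    def test_histmatch_distribution_close_to_reference(self, rng):
        from scipy.stats import ks_2samp

        m = PriorityMap(rng.uniform(0, 1, (32, 32)))
        ref = PriorityMap(rng.beta(2, 5, (32, 32)))
        out = histogram_match(m, ref)
        ks = ks_2samp(out.values.ravel(), ref.values.ravel()).statistic
        assert ks < 1 / 128  # well within bin resolution

    def test_histmatch_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            histogram_match(
                PriorityMap(np.zeros((4, 4))), PriorityMap(np.zeros((5, 5)))
            )


class TestSaliencyAdapter:
    def test_standin_uniform_image_constant(self):
        m = standin_saliency(np.full((32, 32), 0.5))
        assert m.values.max() == pytest.approx(0.0, abs=1e-12)

    def test_standin_bright_disk_peaks_inside(self):
        img = np.zeros((48, 48))
        yy, xx = np.mgrid[:48, :48]
        disk = (yy - 30) ** 2 + (xx - 14) ** 2 <= 36
        img[disk] = 1.0
        m = standin_saliency(img)
        i, j = np.unravel_index(m.values.argmax(), m.shape)
        assert (i - 30) ** 2 + (j - 14) ** 2 <= 100

    def test_save_load_round_trip(self, tmp_path, rng):
        m = PriorityMap(rng.uniform(0, 3, (20, 30)), "UC")
        path = tmp_path / "m.png"
        save_map(m, path)
        back = load_saliency(path, (20, 30))
        np.testing.assert_allclose(back.values, m.values, atol=3.0 / 65535 + 1e-9)
        assert back.variant == "Sal"

    def test_text_round_trip(self, tmp_path, rng):
        m = PriorityMap(rng.uniform(0, 1, (10, 12)))
        path = tmp_path / "m.txt"
        save_map(m, path)
        back = load_saliency(path, (10, 12))
        np.testing.assert_allclose(back.values, m.values, rtol=1e-12)


def test_equal_counts_reduce_to_unit_weight_gaussian_sum(rng):
    # when every box has the same competing count the per-box weights are
    # all 1 and the uncertainty map degenerates to the plain sum of its
    # box Gaussians — the Gaussian-placement analogue of pixel-wise counting
    ds = DetectionSet(
        "im", (48, 48),
        [
            ObjectProposal(BoundingBox(4, 4, 12, 12), {"cup": 0.5, "bowl": 0.1}),
            ObjectProposal(BoundingBox(28, 8, 12, 16), {"fork": 0.4, "car": 0.2}),
            ObjectProposal(BoundingBox(10, 30, 14, 12), {"tv": 0.3, "clock": 0.25}),
        ],
    )
    m = uncertainty_map(ds, PARAMS)
    direct = np.zeros((48, 48))
    for p in ds.proposals:
        direct += gaussian_blob(
            GaussianSpec(p.box.center, p.box.h / 4), (48, 48)
        ).values
    np.testing.assert_allclose(m.values, direct, rtol=1e-9, atol=1e-12)
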