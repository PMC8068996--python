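"""Mode+c*std thresholding, binarization schemes and confusion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import acnsim as a
from acnsim.benchmarks import REFERENCE_ROWS, recall_from_rates
from acnsim.metrics import ConfusionCounts


TOY = np.concatenate([np.full(100, 10), np.full(5, 50)]).astype(np.uint8).reshape(5, 21)


class TestThreshold:
    def test_constant_image_threshold_equals_value(self):
        tp = a.threshold_value(np.full((8, 8), 42, dtype=np.uint8))
        assert tp.pmode == 42 and tp.pstd == 0 and tp.pthresd == 42

    def test_toy_histogram_matches_hand_computation(self):
        tp = a.threshold_value(TOY, c=2.0)
        # oracle: brute-force histogram + population std
        vals = TOY.ravel().astype(float)
        counts = {v: int((vals == v).sum()) for v in set(vals)}
        pmode = min(v for v, n in counts.items() if n == max(counts.values()))
        pstd = float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
        assert tp.pmode == pmode == 10
        assert tp.pstd == pytest.approx(pstd)
        assert tp.pthresd == pytest.approx(27.0, abs=0.1)

    def test_mode_tie_breaks_to_lowest_value(self):
        img = np.concatenate([np.full(10, 10), np.full(10, 50)]).astype(np.uint8)
        assert a.threshold_value(img.reshape(4, 5)).pmode == 10

    def test_float_unit_scale_maps_to_8bit(self):
        img = np.full((4, 4), 10 / 255.0)
        assert a.threshold_value(img).pmode == 10


class TestBinarizeForeground:
    def test_constant_image_all_background(self):
        assert not a.binarize_foreground(np.full((6, 6), 99, dtype=np.uint8)).any()

    def test_toy_image_exactly_bright_pixels(self):
        fg = a.binarize_foreground(TOY, c=2.0)
        np.testing.assert_array_equal(fg, TOY == 50)

    def test_invariant_under_constant_shift(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 100, size=(16, 16)).astype(np.uint8)
        shifted = (img + 40).astype(np.uint8)
        np.testing.assert_array_equal(
            a.binarize_foreground(img), a.binarize_foreground(shifted)
        )


class TestAverageFrames:
    def test_group_of_four_reduces_depth(self):
        stack = np.zeros((64, 8, 8))
        assert a.average_frames(stack, 4).shape == (16, 8, 8)

    def test_groupwise_mean_value(self):
        stack = np.zeros((4, 1, 1))
        stack[3] = 4.0
        assert a.average_frames(stack, 4)[0, 0, 0] == 1.0

    def test_non_divisible_depth_rejected(self):
        with pytest.raises(ValueError):
            a.average_frames(np.zeros((10, 4, 4)), 4)


class TestSimpleAverage:
    def test_single_frame_equals_per_frame_binarization(self):
        rng = np.random.default_rng(8)
        frame = rng.integers(0, 255, size=(16, 16)).astype(np.uint8)
        np.testing.assert_array_equal(
            a.binarize_simple_average(frame[None]),
            a.binarize_foreground(frame),
        )

    def test_constant_frames_give_empty_mask(self):
        assert not a.binarize_simple_average(np.full((5, 8, 8), 30, np.uint8)).any()

    def test_persistent_region_survives_transient_noise(self):
        # a region bright in every frame survives averaging; a patch bright
        # in a single frame is suppressed (verified against the threshold
        # recomputed on the mean image)
        frames = np.full((8, 16, 16), 20, dtype=float)
        frames[:, 4:8, 4:8] = 200.0  # persistent
        frames[0, 12:14, 12:14] = 220.0  # one-frame noise
        mask = a.binarize_simple_average(frames)
        assert mask[4:8, 4:8].all()
        assert not mask[12:14, 12:14].any()


class TestRepeatCount:
    def test_counting_thresholds(self):
        frames = np.full((14, 8, 8), 10, dtype=float)
        frames[:2, 2, 2] = 200.0  # foreground in exactly 2 of 14 frames
        m2, _ = a.binarize_repeat_count(frames, n_repeat=2)
        m3, _ = a.binarize_repeat_count(frames, n_repeat=3)
        assert m2[2, 2] and not m3[2, 2]

    def test_n1_is_union_of_per_frame_foregrounds(self):
        rng = np.random.default_rng(5)
        frames = rng.integers(0, 255, size=(6, 12, 12)).astype(np.uint8)
        m1, _ = a.binarize_repeat_count(frames, n_repeat=1)
        union = np.zeros((12, 12), dtype=bool)
        for f in frames:
            union |= a.binarize_foreground(f)
        np.testing.assert_array_equal(m1, union)

    def test_merged_intensity_is_max_and_binarizes_as_mask(self):
        frames = np.full((5, 6, 6), 10, dtype=float)
        frames[:, 1, 1] = [60, 80, 200, 40, 30]
        mask, merged = a.binarize_repeat_count(frames, n_repeat=2)
        assert merged[1, 1] == 200.0
        np.testing.assert_array_equal(merged > 0, mask)

    @settings(max_examples=30, deadline=None)
    @given(
        arrays(
            np.uint8, (5, 8, 8),
            elements=st.integers(min_value=0, max_value=255),
        )
    )
    def test_masks_monotone_nonincreasing_in_n(self, frames):
        masks = [a.binarize_repeat_count(frames, n_repeat=n)[0] for n in (1, 2, 3)]
        assert not np.any(masks[1] & ~masks[0])
        assert not np.any(masks[2] & ~masks[1])


class TestConfusion:
    def test_perfect_and_inverted_predictions(self):
        gt = np.array([[1, 0], [0, 1]], dtype=bool)
        cc = a.confusion(gt, gt)
        assert cc.fp == cc.fn == 0 and cc.tp == 2 and cc.tn == 2
        cc_inv = a.confusion(~gt, gt)
        assert cc_inv.tp == cc_inv.tn == 0

    def test_counts_match_brute_force_loop(self):
        rng = np.random.default_rng(9)
        pred = rng.random((4, 4)) > 0.5
        gt = rng.random((4, 4)) > 0.5
        cc = a.confusion(pred, gt)
        tp = tn = fp = fn = 0
        for y in range(4):
            for x in range(4):
                if pred[y, x] and gt[y, x]:
                    tp += 1
                elif pred[y, x]:
                    fp += 1
                elif gt[y, x]:
                    fn += 1
                else:
                    tn += 1
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn)
        assert cc.total == 16

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            a.confusion(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_metrics_invariant_under_transposition(self):
        rng = np.random.default_rng(13)
        pred = rng.random((6, 9)) > 0.4
        gt = rng.random((6, 9)) > 0.6
        m1 = a.metrics(a.confusion(pred, gt))
        m2 = a.metrics(a.confusion(pred.T, gt.T))
        assert m1 == m2


class TestMetrics:
    def test_perfect_scores(self):
        m = a.metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_degenerate_conventions(self):
        m = a.metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    @pytest.mark.parametrize(
        "row",
        ["model1_bin1", "model2_bin1", "model2_bin2_n1", "model2_mean"],
    )
    def test_f1_matches_published_rows(self, row):
        r = REFERENCE_ROWS[row]
        f1 = a.f1_from_precision_recall(r["precision"], r["recall"])
        assert f1 == pytest.approx(r["f1"], abs=1e-3)

    @pytest.mark.parametrize(
        "row", [k for k in REFERENCE_ROWS if "bin" in k]
    )
    def test_recall_equals_tp_rate_of_published_rows(self, row):
        r = REFERENCE_ROWS[row]
        assert recall_from_rates(r) == pytest.approx(r["recall"], abs=5e-4)
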