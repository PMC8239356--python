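"""Grain-wise SD-threshold detection, 3-D labelling, watershed and cleanup."""

import numpy as np
import pytest

from astral import ImageStack, cleanup, create_masks, extract_events
from astral.detection import relabel_by_first_voxel


def _stack(data):
    return ImageStack(np.asarray(data, dtype=float))


class TestExtractEvents:
    def test_constant_stack_all_background(self):
        stack = _stack(np.full((10, 8, 8), 42.0))
        assert not extract_events(stack, 1, 5.0).any()

    @pytest.mark.parametrize("k_spike,expected", [(4.0, False), (9.0, True)])
    def test_single_trace_threshold_hand_recomputed(self, k_spike, expected):
        # 100 baseline samples alternating 10 +- 1 (SD 1) and one deflection of
        # k_spike; foreground iff the deflected sample clears mu + 5 sigma of
        # the FULL trace, deflection included.
        trace = 10.0 + np.where(np.arange(101) % 2 == 0, 1.0, -1.0)
        trace[50] = 10.0 + k_spike
        mask = extract_events(_stack(trace[:, None, None]), 1, 5.0)
        mu, sigma = trace.mean(), trace.std()
        assert (trace[50] >= mu + 5 * sigma) == expected
        assert bool(mask[50, 0, 0]) == expected
        assert mask.sum() == (1 if expected else 0)

    def test_block_level_decision_at_grain_4(self):
        # one bright pixel inside a 4x4 block lights up the whole block
        data = np.full((30, 8, 8), 10.0)
        data[15, 1, 2] = 10000.0
        mask = extract_events(_stack(data), 4, 5.0)
        assert mask[15, :4, :4].all()
        assert not mask[15, :4, 4:].any() and not mask[14].any()

    def test_lower_threshold_gives_superset_mask(self):
        rng = np.random.default_rng(0)
        data = 100 + rng.normal(0, 2, size=(60, 32, 32))
        data[20:24, 8:16, 8:16] += 25
        data = np.clip(data, 0, None)
        m5 = extract_events(_stack(data), 4, 5.0)
        m2 = extract_events(_stack(data), 4, 2.0)
        assert (m5 & ~m2).sum() == 0  # threshold-2 mask is a superset
        assert m2.sum() > m5.sum()

    def test_partial_trailing_blocks_covered(self):
        data = np.full((60, 10, 10), 10.0)  # 10 not divisible by grain 4
        data[5, 9, 9] = 10000.0
        mask = extract_events(_stack(data), 4, 5.0)
        assert mask[5, 8:, 8:].all()
        assert mask.shape == data.shape

    def test_grain_larger_than_frame_rejected(self):
        with pytest.raises(ValueError):
            extract_events(_stack(np.ones((5, 8, 8))), 16, 5.0)


class TestCreateMasks:
    def test_empty_mask(self):
        labels = create_masks(np.zeros((4, 4, 4), dtype=bool))
        assert labels.max() == 0

    def test_corner_touch_across_frames_is_one_event(self):
        mask = np.zeros((3, 4, 4), dtype=bool)
        mask[0, 1, 1] = True
        mask[1, 2, 2] = True  # diagonal in y, x AND t: 26-connected
        labels = create_masks(mask)
        assert labels.max() == 1

    def test_oracle_equivalence_random_masks(self, flood_fill_oracle):
        rng = np.random.default_rng(1)
        for density in (0.1, 0.3, 0.5):
            mask = rng.random((12, 12, 12)) < density
            ours = create_masks(mask)
            oracle = flood_fill_oracle(mask)
            # same partition and same scan-order numbering
            np.testing.assert_array_equal(ours, oracle)

    def test_labels_contiguous_and_support_preserved(self):
        rng = np.random.default_rng(2)
        mask = rng.random((10, 16, 16)) < 0.2
        labels = create_masks(mask)
        np.testing.assert_array_equal(labels > 0, mask)
        assert sorted(np.unique(labels[labels > 0])) == list(range(1, labels.max() + 1))


def dumbbell():
    """Two bright 3-D blobs joined by a thin dim bridge: one component,
    two intensity maxima."""
    data = np.full((9, 15, 15), 10.0)
    t, y, x = np.mgrid[0:9, 0:15, 0:15]
    for cy, cx in ((4, 3), (4, 11)):
        data += 100 * np.exp(-((t - 4) ** 2 + (y - cy) ** 2 + (x - cx) ** 2) / 4.0)
    data[4, 4, 3:12] = np.maximum(data[4, 4, 3:12], 40.0)  # the bridge
    mask = data > 35.0
    return ImageStack(data), mask


class TestWatershed:
    def test_dumbbell_splits_only_with_watershed(self):
        stack, mask = dumbbell()
        assert create_masks(mask).max() == 1
        assert create_masks(mask, use_watershed=True, intensities=stack).max() == 2

    def test_watershed_conserves_foreground_voxels(self):
        stack, mask = dumbbell()
        labels = create_masks(mask, use_watershed=True, intensities=stack)
        np.testing.assert_array_equal(labels > 0, mask)

    def test_watershed_regions_are_connected(self, flood_fill_oracle):
        stack, mask = dumbbell()
        labels = create_masks(mask, use_watershed=True, intensities=stack)
        for lab in range(1, labels.max() + 1):
            assert flood_fill_oracle(labels == lab).max() == 1

    def test_watershed_requires_intensities(self):
        with pytest.raises(ValueError):
            create_masks(np.ones((3, 3, 3), dtype=bool), use_watershed=True)


class TestCleanup:
    def test_default_boundary_is_strictly_smaller_than(self):
        # events of volumes 39, 40, 41 at threshold 40 -> 40 and 41 survive
        labels = np.zeros((3, 10, 50), dtype=int)
        labels[0, :3, 0:13].flat[:39] = 1
        labels[1, 4:8, 15:25].flat[:40] = 2
        labels[2, :5, 30:40].flat[:41] = 3
        volumes = np.bincount(labels.ravel())[1:]
        assert volumes.tolist() == [39, 40, 41]
        survivors = cleanup(labels, 40)
        assert np.bincount(survivors.ravel())[1:].tolist() == [40, 41]

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(3)
        labels = create_masks(rng.random((6, 8, 8)) < 0.2)
        np.testing.assert_array_equal(cleanup(labels, 0), labels)

    def test_threshold_above_all_removes_everything(self):
        labels = np.zeros((3, 4, 4), dtype=int)
        labels[0, 0, 0] = 1
        assert cleanup(labels, 1000).max() == 0

    def test_survivors_relabelled_preserving_order(self):
        labels = np.zeros((2, 4, 10), dtype=int)
        labels[0, 0, 0] = 1          # volume 1: removed
        labels[0, 2, 0:5] = 2        # volume 5: kept, becomes 1
        labels[1, 3, 0:7] = 3        # volume 7: kept, becomes 2
        out = cleanup(labels, 2)
        assert out[0, 2, 1] == 1 and out[1, 3, 1] == 2 and out[0, 0, 0] == 0


class TestMonotonicity:
    def test_event_count_non_increasing_in_thresholds(self):
        rng = np.random.default_rng(4)
        data = 100 + rng.normal(0, 3, size=(50, 24, 24))
        data[10:14, 5:12, 5:12] += 30
        data[30:32, 15:20, 15:20] += 25
        stack = _stack(np.clip(data, 0, None))
        masks = [extract_events(stack, 1, k) for k in (2.0, 3.5, 5.0)]
        for lo, hi in zip(masks, masks[1:]):
            assert (hi & ~lo).sum() == 0  # foreground shrinks with sd_threshold
        labels = create_masks(masks[0])
        counts = [cleanup(labels, v).max() for v in (0, 10, 40, 100)]
        assert counts == sorted(counts, reverse=True)


class TestRelabel:
    def test_scan_order_ids_are_deterministic(self):
        labels = np.zeros((2, 3, 3), dtype=int)
        labels[1, 0, 0] = 7
        labels[0, 2, 2] = 3
        out = relabel_by_first_voxel(labels)
        assert out[0, 2, 2] == 1 and out[1, 0, 0] == 2
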