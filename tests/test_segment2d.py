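"""2-D stage: thresholding, erosion, distance transforms, watershed,
object extraction and area classification."""

import numpy as np
import pytest

from somaseg.segment2d import (
    SegmentationParams,
    area_histogram,
    classify_by_area,
    distance_transform,
    erode_diamond,
    global_threshold,
    label_objects,
    watershed_segment,
    segment_frame,
)
from conftest import brute_force_distance


class TestGlobalThreshold:
    @pytest.mark.parametrize(
        "value,t_pct,bit_depth,expected",
        [
            (255, 95.0, 8, True),   # 255 >= 242.25
            (242, 95.0, 8, False),  # just below the 95% cutoff
            (0, 0.1, 8, False),     # zero is below any positive threshold
            (65535, 95.0, 16, True),
        ],
    )
    def test_cutoff_rule(self, value, t_pct, bit_depth, expected):
        frame = np.full((3, 3), value)
        assert bool(global_threshold(frame, t_pct, bit_depth)[0, 0]) is expected

    def test_inclusive_at_exact_cutoff(self):
        # 50% of 255 = 127.5 is not representable; use a 16-bit frame where
        # the cutoff is integral: 25% of 65535 would not be either, so check
        # with a float frame at the exact cutoff value
        frame = np.full((4, 4), 0.95 * 255)
        assert global_threshold(frame, 95.0, 8).all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, size=(32, 32))
        masks = [global_threshold(frame, t, 8) for t in (10, 40, 70, 95)]
        for lo, hi in zip(masks, masks[1:]):
            assert not (hi & ~lo).any(), "raising T must never add foreground"

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            global_threshold(np.zeros((2, 2)), 0.0, 8)


class TestErodeDiamond:
    def test_isolated_pixel_vanishes(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert not erode_diamond(mask).any()

    def test_solid_block_keeps_center_only(self):
        # hand-evaluated: only the center of a 3x3 block has all four
        # diamond neighbors inside the block
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        out = erode_diamond(mask)
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        assert (out == expected).all()

    def test_empty_frame_unchanged(self):
        mask = np.zeros((4, 6), dtype=bool)
        assert not erode_diamond(mask).any()

    def test_border_treated_as_background(self):
        mask = np.ones((3, 3), dtype=bool)
        out = erode_diamond(mask)
        assert out.sum() == 1 and out[1, 1]


class TestDistanceTransform:
    def test_single_foreground_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        for metric in ("euclidean", "chebyshev"):
            d = distance_transform(mask, metric)
            assert d.values[2, 2] == 1.0
            assert (d.values[~mask] == 0).all()

    def test_corner_background_with_border_padding(self):
        # 7x7 all-foreground except (0,0); the implicit background border
        # is closer to interior pixels than the corner hole, so the value
        # at (3,4) is the distance to the frame edge
        mask = np.ones((7, 7), dtype=bool)
        mask[0, 0] = False
        for metric in ("euclidean", "chebyshev"):
            d = distance_transform(mask, metric)
            oracle = brute_force_distance(mask, metric)
            assert np.allclose(d.values, oracle)
            assert d.values[3, 4] == oracle[3, 4] == 3.0

    def test_centered_block_value(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[1:6, 1:6] = True
        for metric in ("euclidean", "chebyshev"):
            assert distance_transform(mask, metric).values[3, 3] == 3.0

    @pytest.mark.parametrize("metric", ["euclidean", "chebyshev"])
    def test_matches_brute_force_on_random_masks(self, metric):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mask = rng.random((16, 16)) < 0.6
            got = distance_transform(mask, metric).values
            assert np.allclose(got, brute_force_distance(mask, metric), atol=1e-9)

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            distance_transform(np.ones((2, 2), dtype=bool), "manhattan")


class TestWatershed:
    def test_two_disjoint_discs_two_labels(self):
        mask = np.zeros((20, 40), dtype=bool)
        rr, cc = np.mgrid[0:20, 0:40]
        mask |= (rr - 10) ** 2 + (cc - 10) ** 2 <= 25
        mask |= (rr - 10) ** 2 + (cc - 30) ** 2 <= 25
        labels = watershed_segment(distance_transform(mask, "euclidean"))
        assert len(np.unique(labels)) - 1 == 2

    def test_dumbbell_splits_at_bridge(self):
        # two 5x5 blocks joined by a 1-px bridge: the bridge is the neckline
        mask = np.zeros((7, 13), dtype=bool)
        mask[1:6, 1:6] = True
        mask[1:6, 7:12] = True
        mask[3, 6] = True
        labels = watershed_segment(distance_transform(mask, "euclidean"))
        assert labels.max() == 2
        left = labels[1:6, 1:6]
        right = labels[1:6, 7:12]
        assert len(np.unique(left[left > 0])) == 1
        assert len(np.unique(right[right > 0])) == 1
        assert np.unique(left[left > 0])[0] != np.unique(right[right > 0])[0]

    def test_single_disc_single_label(self):
        mask = np.zeros((15, 15), dtype=bool)
        rr, cc = np.mgrid[0:15, 0:15]
        mask |= (rr - 7) ** 2 + (cc - 7) ** 2 <= 25
        labels = watershed_segment(distance_transform(mask, "euclidean"))
        assert labels.max() == 1

    def test_partition_and_connectivity_invariants(self):
        from skimage.measure import label as sk_label
        from skimage.morphology import local_maxima

        rng = np.random.default_rng(3)
        for _ in range(10):
            mask = rng.random((24, 24)) < 0.55
            dist = distance_transform(mask, "euclidean")
            labels = watershed_segment(dist)
            # positive labels live only on foreground
            assert not labels[~mask].any()
            # each region is 8-connected
            for lab in np.unique(labels):
                if lab <= 0:
                    continue
                assert sk_label(labels == lab, connectivity=2).max() == 1
            # one label per seed plateau
            n_seeds = sk_label(local_maxima(dist.values, connectivity=2) & mask,
                               connectivity=2).max()
            assert labels.max() == n_seeds


class TestObjectsAndClassification:
    def test_label_objects_basic(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[1:3, 1:3] = 1
        labels[4:6, 4:6] = 2
        objs = label_objects(labels, frame_index=5)
        assert [o.id for o in objs] == [1, 2]
        assert all(o.frame_index == 5 and o.area == 4 for o in objs)

    def test_boundary_of_3x3_square(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1:4, 1:4] = 1
        (obj,) = label_objects(labels, 0)
        expected = {(r, c) for r in range(1, 4) for c in range(1, 4)} - {(2, 2)}
        assert set(obj.boundary) == expected

    def test_area_histogram_bins(self):
        objs = [o for o in _objects_with_areas([3, 5, 120])]
        edges, counts = area_histogram(objs, bin_width=10)
        assert counts[0] == 2
        assert counts[12] == 1
        assert counts.sum() == 3

    def test_area_histogram_single_bin_for_equal_areas(self):
        objs = _objects_with_areas([25, 25, 25])
        _, counts = area_histogram(objs, bin_width=10)
        assert (counts > 0).sum() == 1

    def test_area_histogram_empty(self):
        edges, counts = area_histogram([], bin_width=10)
        assert counts.size == 0

    def test_bimodal_separation_on_synthetic_frame(self, level2_phantom):
        # neurite fragments and somata form two populations separated by a
        # run of empty bins, the basis for choosing alpha from the histogram
        stack, _ = level2_phantom
        params = SegmentationParams(alpha=0.0)
        z = stack.n_frames // 2
        _, cands, frags = segment_frame(stack.frames[z], params, stack.bit_depth, z)
        objs = cands + frags
        edges, counts = area_histogram(objs, bin_width=10)
        areas = sorted(o.area for o in objs)
        assert areas[0] < 40 < areas[-1], "expected both fragments and somata"
        lo = int(np.floor(40 / 10))
        hi = int(np.floor(areas[-1] / 10))
        assert (counts[lo:hi] == 0).any(), "no empty gap between the two modes"

    def test_classification_rule(self):
        objs = _objects_with_areas([3, 5, 120])
        cands, frags = classify_by_area(objs, alpha=60)
        assert [o.area for o in cands] == [120]
        assert sorted(o.area for o in frags) == [3, 5]

    def test_equality_is_soma(self):
        (obj,) = _objects_with_areas([60])
        cands, frags = classify_by_area([obj], alpha=60)
        assert len(cands) == 1 and not frags

    def test_alpha_zero_all_candidates(self):
        objs = _objects_with_areas([1, 2, 3])
        cands, frags = classify_by_area(objs, alpha=0)
        assert len(cands) == 3 and not frags

    def test_partition_and_monotonicity(self):
        rng = np.random.default_rng(9)
        objs = _objects_with_areas(list(rng.integers(1, 200, size=30)))
        prev = None
        for alpha in (0, 10, 50, 100, 250):
            cands, frags = classify_by_area(objs, alpha)
            assert len(cands) + len(frags) == len(objs)
            assert not ({o.id for o in cands} & {o.id for o in frags})
            if prev is not None:
                assert len(cands) <= prev
            prev = len(cands)


def _objects_with_areas(areas):
    from conftest import rect

    out = []
    for i, a in enumerate(areas, start=1):
        out.append(rect(i, 0, 0, 0, 1, int(a)))
    return out
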