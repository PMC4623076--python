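"""Segmentation, skeletonization, path tracing and geodesic lengths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmchains import geodesic_length, segment, skeletonize, trace_paths
from afmchains.segment import smoothed_length

from conftest import make_map


class TestSegment:
    def test_threshold_is_inclusive(self):
        h = np.zeros((16, 16))
        h[8, 4:8] = [0.10, 0.19, 0.20, 0.25]
        mask = segment(make_map(h), threshold=0.2, min_size=1)
        row = mask.labels[8, 4:8]
        assert list(row > 0) == [False, False, True, True]

    def test_empty_map(self):
        mask = segment(make_map(np.zeros((16, 16))))
        assert mask.component_count == 0

    def test_min_size_removes_small_blobs(self):
        h = np.zeros((16, 16))
        h[2, 2:7] = 1.0  # 5 px
        h[10, 10:12] = 1.0  # 2 px
        mask = segment(make_map(h), threshold=0.2, min_size=3)
        assert mask.component_count == 1
        assert np.count_nonzero(mask.labels) == 5

    def test_labels_contiguous(self):
        h = np.zeros((32, 32))
        h[2, 2:12] = 1.0
        h[20, 5:15] = 1.0
        mask = segment(make_map(h), min_size=5)
        assert sorted(np.unique(mask.labels)) == [0, 1, 2]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        hm = make_map(rng.normal(0.3, 0.4, (24, 24)))
        lo = segment(hm, threshold=0.2, min_size=1)
        hi = segment(hm, threshold=0.2 + rng.uniform(0.05, 0.5), min_size=1)
        assert np.all((lo.labels > 0) | (hi.labels == 0))  # hi foreground nested in lo


class TestSkeletonize:
    def test_ribbon_reduces_to_line(self):
        h = np.zeros((24, 32))
        h[10:13, 5:25] = 1.0
        sks = skeletonize(segment(make_map(h), min_size=1))
        assert len(sks) == 1
        sk = sks[0]
        assert len(sk.junctions) == 0
        assert len(sk.endpoints) == 2
        rows, counts = np.unique(sk.pixels[:, 0], return_counts=True)
        # midline of the ribbon, allowing a pixel of thinning jitter at ends
        assert counts.max() >= len(sk.pixels) - 2

    def test_plus_shape_has_one_junction_four_endpoints(self):
        h = np.zeros((32, 32))
        h[14:17, 4:28] = 1.0
        h[4:28, 14:17] = 1.0
        sks = skeletonize(segment(make_map(h), min_size=1))
        assert len(sks) == 1
        sk = sks[0]
        assert len(sk.endpoints) == 4
        assert len(sk.junctions) >= 1  # a junction region (possibly >1 node)

    def test_single_pixel(self):
        h = np.zeros((16, 16))
        h[8, 8] = 1.0
        sks = skeletonize(segment(make_map(h), min_size=1))
        assert len(sks) == 1
        assert len(sks[0].pixels) == 1
        assert all(len(b) <= 1 for b in sks[0].branches)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_skeleton_subset_of_mask(self, seed):
        rng = np.random.default_rng(seed)
        h = (rng.random((24, 24)) < 0.35) * 1.0
        mask = segment(make_map(h), threshold=0.5, min_size=1)
        for sk in skeletonize(mask):
            comp = mask.labels == sk.component_id
            assert all(comp[r, c] for r, c in sk.pixels)


class TestTracePaths:
    def test_straight_line(self):
        h = np.zeros((16, 24))
        h[8, 5:16] = 1.0
        sk = skeletonize(segment(make_map(h), min_size=1))[0]
        out = trace_paths(sk)
        assert len(out["principal"]) == 11

    def test_t_shape_principal_through_long_arms(self):
        h = np.zeros((32, 48))
        h[16, 2:43] = 1.0  # two 20-px arms around col 22
        h[17:23, 22] = 1.0  # 6-px stub (survives 5-px pruning)
        sk = skeletonize(segment(make_map(h), min_size=1))[0]
        pp = trace_paths(sk)["principal"]
        assert len(pp) == 41  # through route, not into the stub
        assert np.all(pp[:, 0] == 16)

    def test_ring_flagged(self):
        h = np.zeros((24, 24))
        h[8:16, 8:16] = 1.0
        h[10:14, 10:14] = 0.0  # annulus
        sk = skeletonize(segment(make_map(h), min_size=1))[0]
        out = trace_paths(sk)
        assert out["principal"] is None
        assert sk.is_ring


class TestGeodesicLength:
    def test_horizontal(self):
        path = np.array([(5, c) for c in range(11)])
        assert geodesic_length(path, 10.0) == pytest.approx(100.0)

    def test_diagonal(self):
        path = np.array([(i, i) for i in range(11)])
        assert geodesic_length(path, 10.0) == pytest.approx(100.0 * np.sqrt(2))

    def test_l_path(self):
        path = np.array([(0, c) for c in range(6)] + [(r, 5) for r in range(1, 6)])
        assert geodesic_length(path, 10.0) == pytest.approx(100.0)

    def test_single_pixel_zero(self):
        assert geodesic_length(np.array([(3, 3)]), 10.0) == 0.0

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError):
            geodesic_length(np.array([(0, 0), (0, 3)]), 10.0)

    def test_matches_bruteforce_step_sum(self):
        # independent oracle: explicit per-step Euclid on the lattice
        rng = np.random.default_rng(7)
        pos = np.array([10, 10])
        path = [tuple(pos)]
        for _ in range(60):
            step = rng.integers(-1, 2, 2)
            if not step.any():
                continue
            pos = pos + step
            if tuple(pos) != path[-1]:
                path.append(tuple(pos))
        path = np.array(path)
        brute = sum(
            float(np.hypot(*(b - a))) for a, b in zip(path, path[1:])
        ) * 7.0
        assert geodesic_length(path, 7.0) == pytest.approx(brute)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([1, 2, 3]))
    def test_rotation_flip_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        pos = np.array([30, 30])
        pts = [tuple(pos)]
        for _ in range(20):
            step = rng.integers(-1, 2, 2)
            if step.any():
                pos = pos + step
                if tuple(pos) != pts[-1]:
                    pts.append(tuple(pos))
        path = np.array(pts)
        base = geodesic_length(path, 10.0)
        # rotate by k*90 degrees about the origin and flip
        rot = {1: lambda p: np.column_stack([p[:, 1], -p[:, 0]]),
               2: lambda p: -p,
               3: lambda p: np.column_stack([-p[:, 1], p[:, 0]])}[k]
        assert geodesic_length(rot(path), 10.0) == pytest.approx(base)
        flipped = np.column_stack([path[:, 0], -path[:, 1]])
        assert geodesic_length(flipped, 10.0) == pytest.approx(base)

    def test_smoothed_length_on_straight_paths(self):
        horiz = np.array([(5, c) for c in range(21)])
        assert smoothed_length(horiz, 10.0) == pytest.approx(200.0, rel=1e-6)
        diag = np.array([(i, i) for i in range(21)])
        assert smoothed_length(diag, 10.0) == pytest.approx(200.0 * np.sqrt(2), rel=1e-6)

    def test_smoothed_length_corrects_staircase_inflation(self):
        # a rasterized line at 22.5 deg: the sqrt-2 metric overestimates,
        # the smoothed estimate should be closer to the true length
        from conftest import raster_polyline

        true = np.hypot(80.0, 80.0 * np.tan(np.radians(22.5))) * 10.0
        path = raster_polyline([(0, 0), (80 * np.tan(np.radians(22.5)), 80)])
        raw = geodesic_length(path, 10.0)
        smooth = smoothed_length(path, 10.0)
        assert abs(smooth - true) < abs(raw - true)
        assert smooth == pytest.approx(true, rel=0.03)
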