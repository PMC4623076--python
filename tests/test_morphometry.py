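"""Per-molecule morphometry: profiles, peaks, bend and complexing angles,
linkage classification."""

import numpy as np
import pytest

from afmchains import (
    HeightProfile,
    bend_angles,
    classify_linkage,
    complexing_angles,
    height_profile,
    peak_to_peak,
)
from afmchains.segment import skeleton_graph

from conftest import make_map, raster_polyline


class TestHeightProfile:
    def test_constant_ridge(self):
        h = np.zeros((16, 32))
        h[8, 4:28] = 3.0
        path = np.array([(8, c) for c in range(4, 28)])
        prof = height_profile(make_map(h), path)
        np.testing.assert_allclose(prof.heights_nm, 3.0)
        assert prof.arc_nm[0] == 0.0

    def test_linear_ramp_exact(self):
        h = np.zeros((16, 48))
        ramp = np.linspace(0, 4, 41)
        h[8, 3:44] = ramp
        path = np.array([(8, c) for c in range(3, 44)])
        prof = height_profile(make_map(h), path)
        np.testing.assert_allclose(prof.heights_nm, ramp)

    def test_background_relative(self):
        # 5 nm ridge over a 2 nm raw background reads 3 nm after flattening
        from afmchains import flatten

        h = np.full((32, 32), 2.0)
        h[4:28, 16] = 5.0  # vertical ridge: one object pixel per scan row
        flat, _ = flatten(make_map(h, frame="raw"))
        path = np.array([(r, 16) for r in range(4, 28)])
        prof = height_profile(flat, path)
        np.testing.assert_allclose(prof.heights_nm, 3.0, atol=0.01)

    def test_out_of_bounds(self):
        with pytest.raises(IndexError):
            height_profile(make_map(np.zeros((16, 16))), np.array([(20, 3)]))


def sinusoid_profile(period=115.8, length=580.0, step=1.0, first_crest=58.0):
    arc = np.arange(0.0, length + step / 2, step)
    h = 4.5 + 1.5 * np.cos(2 * np.pi * (arc - first_crest) / period)
    return HeightProfile(arc_nm=arc, heights_nm=h)


class TestPeakToPeak:
    def test_single_peak_no_distances(self):
        arc = np.arange(0, 200.0, 10.0)
        h = 5.0 * np.exp(-((arc - 100) ** 2) / (2 * 20**2))
        pos, d = peak_to_peak(HeightProfile(arc, h), 4.0)
        assert len(pos) == 1
        assert len(d) == 0

    def test_sinusoid_closed_form_spacing(self):
        # crests at 58 + k*115.8 within 580 nm -> 5 peaks, 4 spacings
        prof = sinusoid_profile()
        pos, d = peak_to_peak(prof, 4.0)
        assert len(pos) == 5
        np.testing.assert_allclose(d, 115.8, atol=1.01)

    def test_two_isolated_peaks(self):
        arc = np.arange(0, 400.0, 2.0)
        h = np.zeros_like(arc)
        h[arc == 100.0] = 5.0
        h[arc == 250.0] = 5.0
        pos, d = peak_to_peak(HeightProfile(arc, h), 4.0, min_peak_gap=10.0)
        np.testing.assert_allclose(d, [150.0])

    def test_threshold_is_strict(self):
        arc = np.arange(0, 100.0, 5.0)
        h = np.full_like(arc, 1.0)
        h[10] = 4.0  # equal to the threshold, not greater
        pos, _ = peak_to_peak(HeightProfile(arc, h), 4.0)
        assert len(pos) == 0

    def test_raising_threshold_never_adds_peaks(self):
        rng = np.random.default_rng(9)
        arc = np.arange(0, 1000.0, 10.0)
        h = 5.0 + rng.normal(0, 1.0, len(arc))
        prof = HeightProfile(arc, h)
        counts = [len(peak_to_peak(prof, thr)[0]) for thr in (3.0, 4.0, 5.0, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_spacings_telescope(self):
        prof = sinusoid_profile()
        pos, d = peak_to_peak(prof, 4.0)
        assert np.sum(d) == pytest.approx(pos[-1] - pos[0])


class TestBendAngles:
    def test_straight_path_empty(self):
        path = np.array([(10, c) for c in range(60)])
        assert bend_angles(path, 10.0) == []

    @pytest.mark.parametrize("true_angle", [90.0, 127.8])
    def test_constructed_vertex(self, true_angle):
        # oracle: arm direction arithmetic fixes the interior angle
        t = np.radians(180.0 - true_angle)
        arm = 400.0 / 10.0  # px
        vertex = np.array([60.0, 60.0])
        start = vertex - np.array([0.0, arm])
        end = vertex + arm * np.array([np.sin(t), np.cos(t)])
        path = raster_polyline([start, vertex, end])
        bends = bend_angles(path, 10.0)
        assert len(bends) == 1
        assert bends[0][1] == pytest.approx(true_angle, abs=2.0)

    def test_shallow_kink_below_deviation_ignored(self):
        t = np.radians(10.0)  # interior 170 deg, deviation below 15
        vertex = np.array([60.0, 60.0])
        path = raster_polyline(
            [vertex - np.array([0, 40.0]), vertex,
             vertex + 40.0 * np.array([np.sin(t), np.cos(t)])]
        )
        assert bend_angles(path, 10.0) == []


class TestComplexingAngles:
    def test_perpendicular_t_junction(self):
        pixels = np.array(
            [(50, c) for c in range(20, 81)] + [(r, 50) for r in range(51, 81)]
        )
        out = complexing_angles(pixels, 10.0)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(90.0, abs=2.0)

    def test_crossing_at_60_reports_obtuse_120(self):
        t = np.radians(60.0)
        a = [(np.array([100.0, 20.0]) + s * np.array([0.0, 1.0])) for s in (0.0, 160.0)]
        b = [(np.array([100.0, 100.0]) + s * np.array([np.sin(t), np.cos(t)]))
             for s in (-70.0, 70.0)]
        pa = raster_polyline(a)
        pb = raster_polyline(b)
        pixels = np.unique(np.vstack([pa, pb]), axis=0)
        out = complexing_angles(pixels, 10.0)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(120.0, abs=2.0)

    def test_t_branch_at_30_reports_150(self):
        t = np.radians(30.0)
        through = raster_polyline([(100.0, 20.0), (100.0, 180.0)])
        branch = raster_polyline(
            [(100.0, 100.0),
             (100.0 + 70.0 * np.sin(t), 100.0 + 70.0 * np.cos(t))]
        )
        pixels = np.unique(np.vstack([through, branch]), axis=0)
        out = complexing_angles(pixels, 10.0)
        assert len(out) == 1
        assert out[0][1] == pytest.approx(150.0, abs=2.0)

    def test_short_branches_excluded(self):
        pixels = np.array(
            [(50, c) for c in range(20, 81)] + [(r, 50) for r in range(51, 53)]
        )
        # the 2-px stub is below window/2 -> junction skipped entirely
        assert complexing_angles(pixels, 10.0) == []


class TestClassifyLinkage:
    def test_overlap_on_doubled_height(self):
        arc = np.arange(0, 600.0, 10.0)
        h = np.full_like(arc, 2.3)
        h[28:31] = 4.6  # 20-30 nm doubled run at a crossing
        link = classify_linkage(HeightProfile(arc, h), n_junctions=1,
                                median_single_height=2.3)
        assert link == "overlap"

    def test_parallel_adherence_on_long_elevated_run(self):
        arc = np.arange(0, 600.0, 10.0)
        h = np.full_like(arc, 2.3)
        h[20:41] = 1.7 * 2.3  # 200 nm co-path
        link = classify_linkage(HeightProfile(arc, h), n_junctions=2,
                                median_single_height=2.3)
        assert link == "parallel_adherence"

    def test_isolated_plain_chain(self):
        arc = np.arange(0, 600.0, 10.0)
        link = classify_linkage(HeightProfile(arc, np.full_like(arc, 2.3)),
                                n_junctions=0, median_single_height=2.3)
        assert link == "isolated"

    def test_rope_needs_junction_free_backbone(self):
        prof = HeightProfile(*_rope_arrays())
        assert classify_linkage(prof, 0, 2.3) == "rope_like"
        assert classify_linkage(prof, 2, 2.3) != "rope_like"


def _rope_arrays():
    arc = np.arange(0, 580.0, 10.0)
    return arc, 4.5 + 1.5 * np.cos(2 * np.pi * (arc - 58.0) / 115.8)
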