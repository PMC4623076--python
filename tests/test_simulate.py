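"""Synthetic topograph generator: backbones, rendering, datasets."""

import dataclasses
import hashlib

import numpy as np
import pytest

from afmchains import (
    SceneSpec,
    flatten,
    generate_dataset,
    render_scene,
    rms_roughness,
    sample_backbone,
)
from afmchains.simulate import _polyline_arcs


class TestSceneSpec:
    def test_defaults_encode_reported_statistics(self):
        s = SceneSpec()
        assert s.height_dist == ("lognormal", 2.3, 0.5)
        assert s.length_dist == ("normal", 640.0, 360.0)
        assert s.bend_angle_deg == (127.8, 25.6)
        assert s.crossing_angle_deg == (114.2, 36.3)
        assert s.period_dist == (115.8, 29.2)
        assert (s.rope_hill_nm, s.rope_crest_nm) == (3.0, 6.0)
        assert s.film_rms_nm == 0.6

    def test_yaml_roundtrip(self, tmp_path):
        s = SceneSpec(n_molecules=5, seed=9)
        p = s.to_yaml(tmp_path / "spec.yaml")
        assert SceneSpec.from_yaml(p) == s

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SceneSpec.from_dict({"n_molecule": 3})

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(crossing_prob=1.5)


class TestSampleBackbone:
    def test_zero_bend_rate_gives_straight_polyline(self):
        spec = SceneSpec(bend_rate=0.0)
        pts, bends = sample_backbone(spec, np.random.default_rng(0), length_nm=500.0)
        assert bends == []
        assert _polyline_arcs(pts)[-1] == pytest.approx(500.0)
        d = np.diff(pts, axis=0)
        cross = np.cross(d[:-1], d[1:]) if len(d) > 1 else np.zeros(1)
        np.testing.assert_allclose(cross, 0.0, atol=1e-9)

    def test_degenerate_bend_distribution(self):
        spec = SceneSpec(bend_rate=1 / 100.0, bend_angle_deg=(127.8, 0.0))
        _, bends = sample_backbone(spec, np.random.default_rng(1), length_nm=1000.0)
        assert len(bends) > 0
        assert all(a == pytest.approx(127.8) for _, a in bends)

    def test_bend_count_matches_rng_replay(self):
        # oracle: replay the same generator draws directly
        spec = SceneSpec(bend_rate=1 / 200.0)
        rng = np.random.default_rng(5)
        _, bends = sample_backbone(spec, rng, length_nm=600.0)
        replay = np.random.default_rng(5)
        s, n = 0.0, 0
        while True:
            s += replay.exponential(200.0)
            if s >= 600.0:
                break
            n += 1
        assert len(bends) == n

    def test_length_truncation(self):
        spec = SceneSpec(length_dist=("normal", 150.0, 300.0), min_length_nm=100.0)
        rng = np.random.default_rng(2)
        for _ in range(50):
            pts, _ = sample_backbone(spec, rng)
            assert _polyline_arcs(pts)[-1] >= 100.0


class TestRenderScene:
    def test_deterministic(self):
        a, _ = render_scene(SceneSpec(seed=3))
        b, _ = render_scene(SceneSpec(seed=3))
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_background_only_rms(self):
        hm, gt = render_scene(SceneSpec(n_molecules=0, seed=7))
        assert len(gt.molecules) == 0
        flat, _ = flatten(hm)
        assert rms_roughness(flat) == pytest.approx(0.6, rel=0.1)

    def test_forced_crossing_heights_add(self):
        spec = SceneSpec(n_molecules=2, crossing_prob=1.0, bend_rate=0.0,
                         film_rms_nm=0.0, row_trend=(0, 0, 0, 0),
                         height_dist=("lognormal", 2.3, 0.0), rope_fraction=0.0,
                         seed=12)
        hm, gt = render_scene(spec)
        assert gt.molecules[1].crossing_partner == 0
        # additive composition; the exact maximum depends on where the
        # crossing falls relative to pixel centres
        assert hm.heights.max() == pytest.approx(4.6, rel=0.05)
        m0, m1 = gt.molecules
        d0 = m0.backbone_nm[-1] - m0.backbone_nm[0]
        d1 = m1.backbone_nm[-1] - m1.backbone_nm[0]
        realized = np.degrees(
            np.arccos(np.clip(np.dot(d0, d1) / np.linalg.norm(d0) / np.linalg.norm(d1), -1, 1))
        )
        assert realized == pytest.approx(m1.crossing_angle_deg, abs=1e-6)

    def test_single_molecule_peak_height_exact(self):
        spec = SceneSpec(n_molecules=1, film_rms_nm=0.0, row_trend=(0, 0, 0, 0),
                         rope_fraction=0.0, bend_rate=0.0, seed=4)
        hm, gt = render_scene(spec)
        assert hm.heights.max() == pytest.approx(gt.molecules[0].peak_height_nm,
                                                 rel=1e-3)

    def test_ground_truth_contour_length_consistent(self):
        _, gt = render_scene(SceneSpec(seed=8))
        for m in gt.molecules:
            assert m.contour_length_nm == pytest.approx(
                _polyline_arcs(m.backbone_nm)[-1], abs=1e-6
            )

    def test_length_draws_distributional_sanity(self):
        # sample mean of 2000 ground-truth lengths within 3 sd/sqrt(n) of the
        # truncated-normal mean
        from scipy import stats

        spec = SceneSpec(bend_rate=0.0)
        rng = np.random.default_rng(123)
        lengths = [
            _polyline_arcs(sample_backbone(spec, rng)[0])[-1] for _ in range(2000)
        ]
        a = (spec.min_length_nm - 640) / 360
        tn = stats.truncnorm(a, np.inf, loc=640, scale=360)
        assert abs(np.mean(lengths) - tn.mean()) < 3 * tn.std() / np.sqrt(2000)

    def test_tip_dilation_widens_but_never_raises(self):
        base = SceneSpec(n_molecules=1, film_rms_nm=0.0, row_trend=(0, 0, 0, 0),
                         rope_fraction=0.0, bend_rate=0.0, seed=4)
        hm0, _ = render_scene(base)
        hm1, _ = render_scene(dataclasses.replace(base, tip_radius=20.0))
        assert hm1.heights.max() <= hm0.heights.max() + 1e-9
        for level in (0.5, 1.0):
            assert np.count_nonzero(hm1.heights > level) >= np.count_nonzero(
                hm0.heights > level
            )


class TestGenerateDataset:
    def test_file_inventory(self, tmp_path):
        spec = SceneSpec(n_molecules=2, seed=1)
        manifest = generate_dataset(spec, 3, tmp_path / "ds")
        files = sorted(p.name for p in (tmp_path / "ds").iterdir())
        assert sum(f.endswith(".tif") for f in files) == 3
        assert sum(f.endswith("_truth.json") for f in files) == 3
        assert manifest.name == "manifest.csv"

    def test_rerun_is_byte_identical(self, tmp_path):
        spec = SceneSpec(n_molecules=2, seed=6)
        m1 = generate_dataset(spec, 2, tmp_path / "a")
        m2 = generate_dataset(spec, 2, tmp_path / "b")
        assert m1.read_text() == m2.read_text()
        for name in ("scene_000.tif", "scene_001.tif"):
            d1 = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
            d2 = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
            assert d1 == d2

    def test_spec_roundtrip_regenerates_identically(self, tmp_path):
        spec = SceneSpec(n_molecules=2, seed=2)
        generate_dataset(spec, 1, tmp_path / "a")
        back = SceneSpec.from_yaml(tmp_path / "a" / "scene_spec.yaml")
        generate_dataset(back, 1, tmp_path / "b")
        assert (tmp_path / "a" / "scene_000.tif").read_bytes() == (
            tmp_path / "b" / "scene_000.tif"
        ).read_bytes()
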