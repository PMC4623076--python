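"""Shared fixtures: constructed rasters and small synthetic scenes."""

import numpy as np
import pytest

from afmchains import HeightMap, SceneSpec
import afmchains.simulate as sim


@pytest.fixture
def flat_map():
    """A blank 64x64 flattened map, 10 nm/px."""
    return HeightMap(np.zeros((64, 64)), pixel_size=10.0, frame="flattened")


def make_map(heights, pixel_size=10.0, frame="flattened"):
    return HeightMap(np.asarray(heights, dtype=float), pixel_size=pixel_size, frame=frame)


def raster_polyline(vertices, step=0.4):
    """8-connected pixel path through float (row, col) vertices."""
    pts = []
    v = np.asarray(vertices, dtype=float)
    for a, b in zip(v, v[1:]):
        seg = b - a
        n = max(2, int(np.ceil(np.linalg.norm(seg) / step)))
        for t in np.linspace(0, 1, n, endpoint=False):
            pts.append(a + t * seg)
    pts.append(v[-1])
    path = [tuple(np.round(p).astype(int)) for p in pts]
    dedup = [path[0]]
    for p in path[1:]:
        if p != dedup[-1]:
            dedup.append(p)
    return np.array(dedup, dtype=np.int64)


def render_molecule_map(backbone_nm, peak_nm=2.3, is_rope=False, period=115.8,
                        phase=0.0, size=(512, 512), pixel_size=10.0):
    """Noise-free flattened map containing a single rendered molecule."""
    spec = SceneSpec(image_size=size, pixel_size=pixel_size, n_molecules=1,
                     film_rms_nm=0.0)
    bb = np.asarray(backbone_nm, dtype=float)
    length = float(np.sum(np.linalg.norm(np.diff(bb, axis=0), axis=1)))
    mol = sim.Molecule(0, bb, length, peak_nm, [], is_rope=is_rope,
                       period_nm=period if is_rope else None,
                       phase_rad=phase if is_rope else None)
    canvas = np.zeros(size)
    sim._render_molecule(canvas, mol, spec)
    return HeightMap(canvas, pixel_size, frame="flattened")
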