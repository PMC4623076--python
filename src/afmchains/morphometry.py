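"""Per-molecule measurements along traced backbones.

Everything the population summary consumes is computed here: the height
profile sampled at each skeleton pixel, peak-to-peak spacings of rope-like
height modulation (local maxima above 4 nm), bending angles of single
chains (windowed tangent fits flanking a flex point), complexing angles at
junctions between assembled chains, and the linkage classification
(isolated / overlap / parallel adherence / rope-like).

Angle conventions: all angles are interior angles in (0°, 180°]. At
crossings the supplementary pair {θ, 180°−θ} cannot be disambiguated from
an unoriented image, so the obtuse member (≥ 90°) is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.signal import find_peaks

from .heightmap import HeightMap
from .segment import arc_positions, geodesic_length, skeleton_graph

__all__ = [
    "HeightProfile",
    "MorphometryRecord",
    "height_profile",
    "peak_to_peak",
    "bend_angles",
    "complexing_angles",
    "classify_linkage",
]

log = logging.getLogger(__name__)

LINKAGE_CLASSES = ("isolated", "overlap", "parallel_adherence", "rope_like")


@dataclass
class HeightProfile:
    """Background-relative heights sampled at each pixel along a path."""

    arc_nm: np.ndarray  # strictly increasing, starts at 0
    heights_nm: np.ndarray
    component_id: int = 0

    def __post_init__(self) -> None:
        self.arc_nm = np.asarray(self.arc_nm, dtype=np.float64)
        self.heights_nm = np.asarray(self.heights_nm, dtype=np.float64)
        if len(self.arc_nm) != len(self.heights_nm):
            raise ValueError("arc/height length mismatch")
        if len(self.arc_nm) and (self.arc_nm[0] != 0.0 or np.any(np.diff(self.arc_nm) <= 0)):
            raise ValueError("arc positions must start at 0 and increase strictly")


@dataclass
class MorphometryRecord:
    """All per-molecule quantities feeding the population summary."""

    component_id: int
    chain_id: int = 0
    length_nm: float = 0.0
    mean_height_nm: float = 0.0
    max_height_nm: float = 0.0
    n_junctions: int = 0
    bend_angles_deg: list = field(default_factory=list)
    bend_positions_nm: list = field(default_factory=list)
    peak_positions_nm: list = field(default_factory=list)
    peak_to_peak_nm: list = field(default_factory=list)
    complexing_angles_deg: list = field(default_factory=list)
    linkage: str = "isolated"
    peeled: bool = False


def height_profile(map: HeightMap, path: np.ndarray) -> HeightProfile:
    """Sample the flattened map at each pixel of an ordered skeleton path.

    Pixel-centre values, no interpolation: the skeleton acts as a mask on
    the image. Arc positions are geodesic (√2-corrected) distances from the
    path's first pixel.
    """
    if map.frame != "flattened":
        raise ValueError("height_profile expects a flattened map")
    path = np.asarray(path)
    if np.any(path < 0) or np.any(path >= np.array(map.shape)):
        raise IndexError("path outside map bounds")
    heights = map.heights[path[:, 0], path[:, 1]]
    return HeightProfile(arc_nm=arc_positions(path, map.pixel_size), heights_nm=heights)


def peak_to_peak(
    profile: HeightProfile,
    peak_threshold: float = 4.0,
    min_peak_gap: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Arc positions of profile maxima above ``peak_threshold`` nm and the
    spacings between consecutive ones.

    Peaks are local maxima strictly greater than the threshold, separated
    by at least ``min_peak_gap`` nm of arc so a flat crest is not counted
    twice. With ≤ 1 peak the spacing list is empty.
    """
    if not peak_threshold > 0:
        raise ValueError("peak_threshold must be > 0 nm")
    h = profile.heights_nm
    if len(h) < 3:
        return np.array([]), np.array([])
    step = float(np.mean(np.diff(profile.arc_nm)))
    dist = max(1, int(np.ceil(min_peak_gap / step)))
    idx, _ = find_peaks(h, height=np.nextafter(peak_threshold, np.inf), distance=dist)
    positions = profile.arc_nm[idx]
    return positions, np.diff(positions)


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Unit direction of a near-straight run of pixels (total least squares),
    sign-aligned with first→last."""
    pts = np.asarray(points, dtype=np.float64)
    sec = pts[-1] - pts[0]
    if len(pts) < 3 or not np.any(sec):
        n = np.linalg.norm(sec)
        return sec / n if n else np.array([1.0, 0.0])
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    d = vt[0]
    if np.dot(d, sec) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between direction vectors, degrees in [0, 180]."""
    c = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return float(np.degrees(np.arccos(c)))


def _smooth_path(path: np.ndarray, window_px: int) -> np.ndarray:
    """Moving-average smoothing of pixel coordinates (straight runs stay
    straight; sub-pixel skeleton jitter is suppressed)."""
    from scipy.ndimage import uniform_filter1d

    if window_px <= 1 or len(path) < window_px + 2:
        return np.asarray(path, dtype=np.float64)
    return np.column_stack(
        [uniform_filter1d(path[:, i].astype(np.float64), window_px, mode="nearest")
         for i in (0, 1)]
    )


def _vertex_angle(
    coords: np.ndarray, arc: np.ndarray, i: int, window: float, gap: float = 0.0
) -> float:
    """Interior angle at vertex i from straight fits to the two flanking
    arc-length windows (180° = straight).

    With ``gap`` > 0 the fit arms span [gap, gap+window] nm away from the
    vertex on each side, leaving out the corner zone where the raster
    skeleton (and any coordinate smoothing) rounds the flex.
    """
    before = coords[(arc >= arc[i] - gap - window) & (arc <= arc[i] - gap)]
    after = coords[(arc >= arc[i] + gap) & (arc <= arc[i] + gap + window)]
    if len(before) < 2 or len(after) < 2:
        return 180.0
    u = _fit_direction(before)  # points toward the vertex
    v = _fit_direction(after)  # points away from the vertex
    return 180.0 - _angle_between(u, v)


def bend_angles(
    path: np.ndarray,
    pixel_size: float,
    window: float = 50.0,
    min_bend_deviation: float = 15.0,
    smooth_px: int = 5,
    confirm_factor: float = 3.0,
    refine_gap: float = 20.0,
    refine_window: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Bending angles along a single chain.

    At each candidate vertex the two flanking path segments of arc length
    ``window`` nm are fitted with straight directions; the interior angle
    between them is 180° on a straight chain and decreases at a flex.
    Reported bends are local minima of the interior angle whose deviation
    from straight, 180° − angle, is at least ``min_bend_deviation``.

    Detection and measurement are separated, which matters on noisy
    images. Candidate flexes are found on coordinates smoothed over
    ``smooth_px`` pixels (suppressing skeleton jitter) and must persist
    when re-measured with a window ``confirm_factor`` times larger — a
    molecular bend is scale-free, whereas tracing wobble lives at the
    background correlation scale and decays when the window grows well
    past it. The reported angle is then re-fitted with arms
    spanning [refine_gap, refine_gap+refine_window] nm from the vertex
    (default refine_window = 1.6·window), because arms that touch the
    vertex average over the rounded corner and read too straight.

    Returns (arc_position_nm, angle_deg) pairs; empty for paths shorter
    than twice the window.
    """
    path = np.asarray(path)
    arc = arc_positions(path, pixel_size)
    total = arc[-1] if len(arc) else 0.0
    if total < 2 * window:
        return []
    cand = np.nonzero((arc >= window) & (arc <= total - window))[0]
    if len(cand) == 0:
        return []
    coords = _smooth_path(path, smooth_px)
    if refine_window is None:
        refine_window = 1.6 * window
    angles = np.array([_vertex_angle(coords, arc, i, window) for i in cand])
    deviation = 180.0 - angles
    step = total / max(len(arc) - 1, 1)
    idx, _ = find_peaks(
        deviation,
        height=min_bend_deviation,
        distance=max(1, int(np.round(window / step))),
    )
    out = []
    for i in idx:
        vi = cand[i]
        if confirm_factor > 1.0:
            big = min(
                confirm_factor * window, float(arc[vi]), float(total - arc[vi])
            )
            if big < 1.5 * window:
                continue  # too close to an end to confirm — stay conservative
            conf = _vertex_angle(coords, arc, vi, big)
            if 180.0 - conf < min_bend_deviation:
                continue
        refined = _vertex_angle(coords, arc, vi, refine_window, gap=refine_gap)
        if 180.0 - refined < min_bend_deviation:
            continue
        out.append((float(arc[vi]), float(refined)))
    return out


def _junction_clusters(g: nx.Graph, merge_px: float = 5.0) -> list[set]:
    """Group junction nodes lying within ``merge_px`` geodesic pixels of each
    other into single junction regions (thinning splits an X crossing into
    two nearby Y nodes)."""
    junctions = [n for n in g.nodes if g.degree(n) >= 3]
    if not junctions:
        return []
    jg = nx.Graph()
    jg.add_nodes_from(junctions)
    for i, a in enumerate(junctions):
        lengths = nx.single_source_dijkstra_path_length(g, a, cutoff=merge_px, weight="weight")
        for b in junctions[i + 1:]:
            if b in lengths:
                jg.add_edge(a, b)
    return [set(c) for c in nx.connected_components(jg)]


def _incident_directions(
    g: nx.Graph,
    cluster: set,
    pixel_size: float,
    window: float,
    branch_score: Optional[np.ndarray] = None,
    min_branch_score: float = 0.0,
    fit_gap: float = 20.0,
) -> list[np.ndarray]:
    """Tangent directions (unit vectors, pointing away from the junction) of
    every branch leaving a junction cluster.

    Each direction is fitted over the branch's [fit_gap, fit_gap+window] nm
    of path: the first stretch next to the junction is skipped because the
    raster skeleton of two merging ridges is distorted there (the same gap
    rule the bend estimator applies at a flex). Branches shorter than half
    that span are excluded, as are branches whose median ``branch_score``
    falls below ``min_branch_score`` (film spurs attached to a molecule
    are not assembly partners)."""
    dirs = []
    boundary = [
        (n, nbr) for n in cluster for nbr in g.neighbors(n) if nbr not in cluster
    ]
    span = fit_gap + window
    for start, first in boundary:
        # walk outward until span nm, a junction, or an endpoint
        pathpts = [start, first]
        arc = g.edges[start, first]["weight"] * pixel_size
        prev, cur = start, first
        while arc < span:
            nbrs = [n for n in g.neighbors(cur) if n != prev and n not in cluster]
            if g.degree(cur) >= 3 or not nbrs:
                break
            nxt = nbrs[0]
            arc += g.edges[cur, nxt]["weight"] * pixel_size
            prev, cur = cur, nxt
            pathpts.append(cur)
        if arc < span / 2:
            log.debug("junction branch shorter than %.0f nm excluded", span / 2)
            continue
        pts = np.asarray(pathpts)
        if branch_score is not None:
            med = float(np.median(branch_score[pts[1:, 0], pts[1:, 1]]))
            if med < min_branch_score:
                log.debug("junction branch below score gate excluded")
                continue
        fpts = pts.astype(float)
        arcs = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(fpts, axis=0), axis=1))]
        ) * pixel_size
        sel = fpts[arcs >= fit_gap]
        if len(sel) < 2:
            sel = fpts[-2:]
        dirs.append(_fit_direction(sel))
    return dirs


def _obtuse(theta: float) -> float:
    """The member of the supplementary pair {θ, 180−θ} that is ≥ 90°."""
    return theta if theta >= 90.0 else 180.0 - theta


def complexing_angles(
    skeleton_pixels: np.ndarray,
    pixel_size: float,
    window: float = 50.0,
    merge_px: float = 5.0,
    graph: Optional[nx.Graph] = None,
    branch_score: Optional[np.ndarray] = None,
    min_branch_score: float = 0.0,
) -> list[tuple[tuple[float, float], float]]:
    """Angles at which assembled chains meet, one per junction region.

    For a 3-branch junction (an end linked to the middle of another chain)
    the through-chain is the most antiparallel branch pair; the reported
    angle is the obtuse angle between the terminating branch and the
    through-chain. For a 4-branch crossing, branches are paired into two
    chain axes (most antiparallel pairing) and the obtuse angle between the
    axes is reported. Junctions of other multiplicity are skipped.

    Returns ((row, col) junction centroid in pixels, angle_deg) pairs.
    """
    g = graph if graph is not None else skeleton_graph(np.asarray(skeleton_pixels))
    results = []
    for cluster in _junction_clusters(g, merge_px=merge_px):
        dirs = _incident_directions(
            g, cluster, pixel_size, window,
            branch_score=branch_score, min_branch_score=min_branch_score,
        )
        centroid = tuple(np.mean(np.array(sorted(cluster), dtype=float), axis=0))
        if len(dirs) == 3:
            # through pair = most antiparallel two branches
            pairs = [(0, 1), (0, 2), (1, 2)]
            i, j = min(pairs, key=lambda p: float(np.dot(dirs[p[0]], dirs[p[1]])))
            (k,) = set(range(3)) - {i, j}
            axis = dirs[i] - dirs[j]
            angle = _obtuse(_angle_between(dirs[k], axis))
        elif len(dirs) == 4:
            pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
            def antiparallel(p):
                (a, b), (c, d) = p
                return float(np.dot(dirs[a], dirs[b]) + np.dot(dirs[c], dirs[d]))
            (a, b), (c, d) = min(pairings, key=antiparallel)
            axis1 = dirs[a] - dirs[b]
            axis2 = dirs[c] - dirs[d]
            angle = _obtuse(_angle_between(axis1, axis2))
        else:
            log.debug("junction with %d usable branches skipped", len(dirs))
            continue
        results.append((centroid, float(angle)))
    return results


def _elevated_runs(profile: HeightProfile, level: float) -> list[tuple[float, float]]:
    """(start_nm, length_nm) of maximal runs with height >= level."""
    above = profile.heights_nm >= level
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append((float(profile.arc_nm[i]), float(profile.arc_nm[j] - profile.arc_nm[i])))
            i = j + 1
        else:
            i += 1
    return runs


def classify_linkage(
    profile: HeightProfile,
    n_junctions: int,
    median_single_height: float,
    peak_threshold: float = 4.0,
    min_peak_gap: float = 20.0,
    overlap_factor: float = 1.6,
    parallel_min_run: float = 50.0,
) -> str:
    """Assign the assembly class of one traced chain.

    ``rope_like``: a junction-free backbone with ≥ 3 maxima passing the
    peak rule (crest/hill alternation of two intertwined chains — the
    assembly reads as a single fibre, so branching disqualifies it).
    ``parallel_adherence``: the profile stays above overlap_factor × the
    median single-chain height for ≥ ``parallel_min_run`` nm (chains
    adherent along a distance). ``overlap``: a junction whose
    neighbourhood height reaches that level over a shorter run (one chain
    lying across another roughly doubles the height at the linking point).
    ``isolated`` otherwise.
    """
    peaks, _ = peak_to_peak(profile, peak_threshold, min_peak_gap)
    if n_junctions == 0 and len(peaks) >= 3:
        return "rope_like"
    if median_single_height <= 0:
        return "isolated"  # no height reference — elevation is undefined
    level = overlap_factor * median_single_height
    runs = _elevated_runs(profile, level)
    if any(r[1] >= parallel_min_run for r in runs):
        return "parallel_adherence"
    if n_junctions > 0 and (runs or float(np.max(profile.heights_nm, initial=0.0)) >= level):
        return "overlap"
    return "isolated"
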