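"""End-to-end protocol: flatten → segment → skeletonize → extract chains →
morphometry → population summary, plus the ground-truth recovery report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import morphometry as morpho
from .chains import Chain, ChainParams, extract_chains, ridge_contrast
from .heightmap import HeightMap, flatten, read_heightmap, rms_roughness
from .morphometry import MorphometryRecord, classify_linkage, complexing_angles
from .population import PopulationSummary, summarize
from .segment import segment
from .simulate import GroundTruth, SceneSpec

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "analyze_map", "recovery_report"]


@dataclass
class PipelineConfig:
    """Every stage parameter in one serializable bundle."""

    flatten_order: int = 3
    threshold_nm: float = 0.2
    min_size_px: int = 20
    prune_length_px: float = 5.0
    peak_threshold_nm: float = 4.0
    min_peak_gap_nm: float = 40.0
    bend_window_nm: float = 50.0
    min_bend_deviation_deg: float = 15.0
    complexing_window_nm: float = 50.0
    junction_merge_px: float = 5.0
    overlap_factor: float = 1.6
    parallel_min_run_nm: float = 50.0
    display_length_cap_nm: float = 2000.0
    seed: int = 1
    chains: ChainParams = field(default_factory=ChainParams)
    scene: SceneSpec = field(default_factory=SceneSpec)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scene"] = self.scene.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "scene" in d and isinstance(d["scene"], dict):
            d["scene"] = SceneSpec.from_dict(d["scene"])
        if "chains" in d and isinstance(d["chains"], dict):
            known_c = {f.name for f in dataclasses.fields(ChainParams)}
            unknown_c = set(d["chains"]) - known_c
            if unknown_c:
                raise ValueError(f"unknown chain-extraction keys: {sorted(unknown_c)}")
            d["chains"] = ChainParams(**d["chains"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    records: list[MorphometryRecord]
    profiles: dict  # chain_id -> HeightProfile
    paths: dict  # chain_id -> ordered (n, 2) pixel path
    image_of: dict  # chain_id -> index of the source image
    summary: Optional[PopulationSummary]
    per_image: list[dict]
    background_rms: list[float]

    @property
    def n_chains(self) -> int:
        return len(self.records)


def analyze_map(
    hm: HeightMap, config: PipelineConfig, chain_id_offset: int = 0
) -> tuple[list[MorphometryRecord], dict, dict]:
    """Run all per-image stages on one raw height map.

    Returns (records, profiles-by-chain_id, paths-by-chain_id, stage-count
    dict). Linkage classes need the population median single-chain height,
    so :func:`run_pipeline` classifies after pooling all images.
    """
    flat, bgmodel = flatten(hm, order=config.flatten_order,
                            object_threshold=config.threshold_nm)
    mask = segment(flat, threshold=config.threshold_nm, min_size=config.min_size_px)
    chains = extract_chains(flat, mask, config.chains)
    _, score = ridge_contrast(flat, config.chains.median_window_px)
    records: list[MorphometryRecord] = []
    profiles: dict = {}
    paths: dict = {}
    for ch in chains:
        cid = ch.chain_id + chain_id_offset
        prof = ch.profile
        peaks, spacings = morpho.peak_to_peak(
            prof, config.peak_threshold_nm, config.min_peak_gap_nm
        )
        if ch.n_junctions == 0:
            bends = morpho.bend_angles(
                ch.path, hm.pixel_size, config.bend_window_nm,
                config.min_bend_deviation_deg,
            )
            # a flex measured where the ridge signal collapses is a tracing
            # artifact (bridged gap), not a molecular bend
            arc = morpho.arc_positions(ch.path, hm.pixel_size)
            kept_bends = []
            for pos, ang in bends:
                i_v = int(np.argmin(np.abs(arc - pos)))
                nb = ch.path[max(0, i_v - 2):i_v + 3]
                if np.min(score[nb[:, 0], nb[:, 1]]) >= config.chains.chain_gate_nm:
                    kept_bends.append((pos, ang))
            bends = kept_bends
        else:
            bends = []
        cplx = complexing_angles(
            None, hm.pixel_size,
            window=config.complexing_window_nm,
            merge_px=config.junction_merge_px,
            graph=ch.graph,
            branch_score=score,
            min_branch_score=config.chains.chain_gate_nm,
        ) if ch.n_junctions > 0 else []
        records.append(
            MorphometryRecord(
                component_id=ch.component_id,
                chain_id=cid,
                length_nm=ch.length_nm,
                mean_height_nm=float(prof.heights_nm.mean()),
                max_height_nm=float(prof.heights_nm.max()),
                n_junctions=ch.n_junctions,
                bend_angles_deg=[a for (_, a) in bends],
                bend_positions_nm=[p for (p, _) in bends],
                peak_positions_nm=list(map(float, peaks)),
                peak_to_peak_nm=list(map(float, spacings)),
                complexing_angles_deg=[a for (_, a) in cplx],
                peeled=ch.peeled,
            )
        )
        profiles[cid] = prof
        paths[cid] = ch.path
    counts = {
        "components": mask.component_count,
        "chains": len(records),
        "junctions": int(sum(r.n_junctions > 0 for r in records)),
        "background_rms_nm": rms_roughness(flat, bgmodel.background_mask),
    }
    return records, profiles, paths, counts


def _classify_all(records: list[MorphometryRecord], profiles: dict,
                  config: PipelineConfig) -> None:
    single_means = [
        r.mean_height_nm for r in records if r.n_junctions == 0 and not r.peeled
    ]
    if not single_means:  # no complete singles; any chain is better than none
        single_means = [r.mean_height_nm for r in records]
    median_h = float(np.median(single_means)) if single_means else 0.0
    for r in records:
        r.linkage = classify_linkage(
            profiles[r.chain_id],
            r.n_junctions,
            median_h,
            peak_threshold=config.peak_threshold_nm,
            min_peak_gap=config.min_peak_gap_nm,
            overlap_factor=config.overlap_factor,
            parallel_min_run=config.parallel_min_run_nm,
        )


def run_pipeline(
    config: PipelineConfig,
    inputs: Sequence[str | Path] | Sequence[HeightMap],
    out_dir: Optional[str | Path] = None,
    pixel_size: Optional[float] = None,
) -> PipelineResult:
    """Run the full protocol over a set of height maps and pool the results.

    ``inputs`` may be file paths (TIFF/text) or in-memory HeightMaps.
    When ``out_dir`` is given, writes molecules.csv, profiles.csv and
    summary.json there.
    """
    all_records: list[MorphometryRecord] = []
    all_profiles: dict = {}
    all_paths: dict = {}
    image_of: dict = {}
    per_image = []
    bg_rms = []
    offset = 0
    for img_idx, item in enumerate(inputs):
        hm = item if isinstance(item, HeightMap) else read_heightmap(item, pixel_size)
        records, profiles, paths, counts = analyze_map(hm, config, chain_id_offset=offset)
        offset += len(records)
        log.info("%s: %d components, %d chains, %d with junctions",
                 hm.source_id, counts["components"], counts["chains"], counts["junctions"])
        all_records.extend(records)
        all_profiles.update(profiles)
        all_paths.update(paths)
        image_of.update({cid: img_idx for cid in profiles})
        counts["source_id"] = hm.source_id
        per_image.append(counts)
        bg_rms.append(counts["background_rms_nm"])
    if all_records:
        _classify_all(all_records, all_profiles, config)
        summary = summarize(
            all_records, all_profiles, display_length_cap=config.display_length_cap_nm
        )
    else:
        summary = None
    result = PipelineResult(
        records=all_records,
        profiles=all_profiles,
        paths=all_paths,
        image_of=image_of,
        summary=summary,
        per_image=per_image,
        background_rms=bg_rms,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in result.records:
        d = asdict(r)
        for k in ("bend_angles_deg", "bend_positions_nm", "peak_positions_nm",
                  "peak_to_peak_nm", "complexing_angles_deg"):
            d[k] = json.dumps(d[k])
        rows.append(d)
    pd.DataFrame(rows).to_csv(out / "molecules.csv", index=False)
    prof_rows = []
    for cid, prof in result.profiles.items():
        for a, hh in zip(prof.arc_nm, prof.heights_nm):
            prof_rows.append({"chain_id": cid, "arc_nm": a, "height_nm": hh})
    pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
    summary_obj = result.summary.as_dict() if result.summary else {"n_chains_total": 0}
    summary_obj["per_image"] = result.per_image
    (out / "summary.json").write_text(json.dumps(summary_obj, indent=2))


# ---------------------------------------------------------------------------
# ground-truth recovery


def _densify(pts: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline so consecutive points are at most ``step`` apart."""
    out = [pts[0]]
    for p, q in zip(pts, pts[1:]):
        seg = np.linalg.norm(q - p)
        n = max(1, int(np.ceil(seg / step)))
        for k in range(1, n + 1):
            out.append(p + (q - p) * k / n)
    return np.array(out)


def recovery_report(
    result: PipelineResult,
    truths: Sequence[GroundTruth],
    pixel_size: float,
    match_tol_nm: float = 50.0,
) -> pd.DataFrame:
    """Match measured chains to ground-truth molecules and report errors.

    Each measured chain is assigned the ground-truth molecule (same image)
    with the smallest mean nearest-point distance between the chain's
    skeleton pixels and the molecule's backbone polyline; matches beyond
    ``match_tol_nm`` are dropped. One row per match with length/height
    errors and linkage agreement. Raises if more than half of the
    non-assembled ground-truth molecules go unmatched — a pipeline
    regression guard.
    """
    from scipy.spatial import cKDTree

    rows = []
    n_truth = sum(
        1 for t in truths for m in t.molecules if m.linkage == "isolated"
    )
    trees = []
    for truth in truths:
        trees.append(
            {
                m.molecule_id: cKDTree(_densify(m.backbone_nm, pixel_size / 2))
                for m in truth.molecules
            }
        )
    for r in result.records:
        img = result.image_of[r.chain_id]
        if img >= len(truths):
            raise ValueError("fewer ground truths than images in the run")
        truth = truths[img]
        mols = {m.molecule_id: m for m in truth.molecules}
        chain_pts = np.asarray(result.paths[r.chain_id], dtype=float) * pixel_size
        best = (np.inf, None)
        for mid, tree in trees[img].items():
            d = float(tree.query(chain_pts)[0].mean())
            if d < best[0]:
                best = (d, mid)
        if best[1] is None or best[0] > match_tol_nm:
            continue
        m = mols[best[1]]
        rows.append(
            {
                "image": img,
                "chain_id": r.chain_id,
                "molecule_id": m.molecule_id,
                "match_dist_nm": best[0],
                "true_length_nm": m.contour_length_nm,
                "measured_length_nm": r.length_nm,
                "length_error_nm": r.length_nm - m.contour_length_nm,
                "true_peak_height_nm": m.peak_height_nm,
                "measured_mean_height_nm": r.mean_height_nm,
                "true_linkage": m.linkage,
                "measured_linkage": r.linkage,
            }
        )
    df = pd.DataFrame(rows)
    if n_truth > 0:
        matched = (
            df[df["true_linkage"] == "isolated"]
            .groupby("image")["molecule_id"].nunique().sum()
            if len(df) else 0
        )
        if matched < 0.5 * n_truth:
            raise RuntimeError(
                f"only {matched}/{n_truth} isolated ground-truth molecules matched"
            )
    return df
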