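"""Population distributions over per-molecule records.

The study-level summary: a log-normal fit to pooled skeleton-pixel heights
(AFM molecule "diameter" is read from height, not width, because tip
convolution broadens laterally but preserves crests), a Gaussian fit to
per-chain contour lengths, and Gaussian summaries for peak-to-peak periods,
bending angles and complexing angles. Fits are maximum likelihood; the
goodness quoted alongside is the R² between the histogram and the fitted
density integrated over the same bins, since histograms are how such
distributions are displayed and compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .morphometry import MorphometryRecord

__all__ = ["QuantitySummary", "PopulationSummary", "fit_distribution", "summarize"]

FAMILIES = ("gaussian", "lognormal")


class DegenerateFitError(ValueError):
    """Samples have zero variance; no two-parameter fit is identifiable."""


@dataclass
class QuantitySummary:
    """Fitted population parameters for one measured quantity."""

    mean: float
    sd: float
    n_points: int  # N_p: data values pooled
    n_chains: int  # N: chains contributing
    fit_family: Optional[str] = None
    fit_params: Optional[dict] = None
    r_squared: Optional[float] = None
    hist_edges: Optional[list] = None
    hist_counts: Optional[list] = None

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "N_p": self.n_points,
            "N": self.n_chains,
            "fit_family": self.fit_family,
            "fit_params": self.fit_params,
            "r_squared": self.r_squared,
            "hist_edges": self.hist_edges,
            "hist_counts": self.hist_counts,
        }


@dataclass
class PopulationSummary:
    """Machine twin of the study-style characterization table."""

    height: Optional[QuantitySummary] = None
    length: Optional[QuantitySummary] = None
    peak_to_peak: Optional[QuantitySummary] = None
    bend_angle: Optional[QuantitySummary] = None
    complexing_angle: Optional[QuantitySummary] = None
    n_chains_total: int = 0
    linkage_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_chains_total": self.n_chains_total,
            "linkage_counts": self.linkage_counts,
            **{
                q: (getattr(self, q).as_dict() if getattr(self, q) else None)
                for q in ("height", "length", "peak_to_peak", "bend_angle", "complexing_angle")
            },
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(), indent=2, **kw)


def _histogram_r2(samples: np.ndarray, dist, bins: int) -> tuple[float, np.ndarray, np.ndarray]:
    counts, edges = np.histogram(samples, bins=bins)
    expected = len(samples) * np.diff(dist.cdf(edges))
    ss_res = float(np.sum((counts - expected) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, edges, counts


def fit_distribution(
    samples: Sequence[float], family: str, bins: int = 20
) -> tuple[dict, float]:
    """Maximum-likelihood fit of a Gaussian or log-normal to a sample.

    Returns (fit_params, r_squared). ``fit_params`` always carries the
    arithmetic ``mean`` and ``sd`` of the fitted distribution — for the
    log-normal these are derived from the (µ, σ) of the log, matching how
    height statistics are quoted as plain mean (sd).
    """
    x = np.asarray(samples, dtype=np.float64)
    if len(x) < 20:
        raise ValueError(f"need >= 20 samples, got {len(x)}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all samples identical")
    if family == "lognormal":
        if np.any(x <= 0):
            raise ValueError("log-normal requires strictly positive samples")
        logx = np.log(x)
        mu, sigma = float(logx.mean()), float(logx.std())
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        mean = float(np.exp(mu + sigma**2 / 2))
        sd = float(mean * np.sqrt(np.expm1(sigma**2)))
        params = {"mu_log": mu, "sigma_log": sigma, "mean": mean, "sd": sd}
    else:
        mu, sigma = float(x.mean()), float(x.std())
        dist = stats.norm(loc=mu, scale=sigma)
        params = {"mean": mu, "sd": sigma}
    r2, _, _ = _histogram_r2(x, dist, bins)
    return params, r2


def _summarize_samples(
    values: np.ndarray,
    n_chains: int,
    family: Optional[str],
    bins: int = 20,
    hist_values: Optional[np.ndarray] = None,
) -> Optional[QuantitySummary]:
    values = np.asarray(values, dtype=np.float64)
    if len(values) == 0:
        return None
    hist_values = values if hist_values is None else np.asarray(hist_values)
    mean, sd = float(values.mean()), float(values.std())
    fit_params = r2 = None
    fam = None
    if family is not None and len(values) >= 20 and np.ptp(values) > 0:
        if family == "lognormal":
            values = values[values > 0]
        try:
            fit_params, r2 = fit_distribution(values, family, bins=bins)
            mean, sd = fit_params["mean"], fit_params["sd"]
            fam = family
        except (ValueError, DegenerateFitError):
            pass
    counts, edges = np.histogram(hist_values, bins=bins) if len(hist_values) else (None, None)
    return QuantitySummary(
        mean=mean,
        sd=sd,
        n_points=int(len(values)),
        n_chains=int(n_chains),
        fit_family=fam,
        fit_params=fit_params,
        r_squared=r2,
        hist_edges=None if edges is None else edges.tolist(),
        hist_counts=None if counts is None else counts.tolist(),
    )


def summarize(
    records: Sequence[MorphometryRecord],
    profiles: Optional[dict] = None,
    display_length_cap: float = 2000.0,
    bins: int = 20,
) -> PopulationSummary:
    """Pool per-molecule records into the population summary.

    Height points (every skeleton pixel) and contour lengths come from
    complete single molecules only — isolated, junction-free, not an arm
    peeled off an assembly — because assembled chains would inflate the
    heights and truncated arms would deflate the lengths, exactly the
    effects the characterization excludes. Bend angles are pooled over the
    same single molecules, complexing angles over all junction-bearing
    chains, and peak-to-peak spacings over rope-like chains. Chains longer
    than ``display_length_cap`` stay in the statistics but are dropped
    from the length histogram display only.

    ``profiles`` maps chain_id → HeightProfile; without it the height pool
    falls back to per-chain mean heights.
    """
    if not records:
        raise ValueError("no records to summarize")
    singles = [
        r for r in records
        if r.linkage == "isolated" and r.n_junctions == 0 and not r.peeled
    ]

    if profiles:
        height_pool = np.concatenate(
            [profiles[r.chain_id].heights_nm for r in singles if r.chain_id in profiles]
        ) if singles else np.array([])
    else:
        height_pool = np.array([r.mean_height_nm for r in singles])
    height_pool = height_pool[height_pool > 0]

    lengths = np.array([r.length_nm for r in singles])
    bends = np.concatenate([r.bend_angles_deg for r in singles]) if singles else np.array([])
    n_bend_chains = sum(1 for r in singles if len(r.bend_angles_deg))
    ropes = [r for r in records if r.linkage == "rope_like"]
    p2p = np.concatenate([r.peak_to_peak_nm for r in ropes]) if ropes else np.array([])
    n_p2p_chains = sum(1 for r in ropes if len(r.peak_to_peak_nm))
    cplx = np.concatenate(
        [r.complexing_angles_deg for r in records]
    ) if records else np.array([])
    n_cplx_chains = sum(1 for r in records if len(r.complexing_angles_deg))

    linkage_counts: dict = {}
    for r in records:
        linkage_counts[r.linkage] = linkage_counts.get(r.linkage, 0) + 1

    return PopulationSummary(
        height=_summarize_samples(height_pool, len(singles), "lognormal", bins),
        length=_summarize_samples(
            lengths, len(singles), "gaussian", bins,
            hist_values=lengths[lengths <= display_length_cap] if len(lengths) else lengths,
        ),
        peak_to_peak=_summarize_samples(p2p, n_p2p_chains, "gaussian", bins),
        bend_angle=_summarize_samples(bends, n_bend_chains, "gaussian", bins),
        complexing_angle=_summarize_samples(cplx, n_cplx_chains, "gaussian", bins),
        n_chains_total=len(records),
        linkage_counts=linkage_counts,
    )
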