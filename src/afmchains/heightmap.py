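"""Height-map container, file I/O and background flattening.

AFM topographs arrive as 2D grids of surface heights (nm). Before any
morphometry the scanner background must be removed so that object heights
are measured relative to the surrounding film/mica: each scan row is fitted
with a low-order polynomial (order 3 by default, the standard line-wise
"flattening") over background pixels and the fit is subtracted.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

__all__ = [
    "HeightMap",
    "BackgroundModel",
    "read_heightmap",
    "write_heightmap",
    "flatten",
    "rms_roughness",
]

MIN_GRID = 16
#: minimum fraction of a scan row that must remain background for a valid fit
MIN_BACKGROUND_FRACTION = 0.20


class FormatError(ValueError):
    """Input grid is not a rectangular single-channel height map."""


class DataError(ValueError):
    """Height values are non-finite or otherwise unusable."""


class MetadataError(ValueError):
    """Required metadata (pixel size) is missing."""


class FlattenError(RuntimeError):
    """Background fit could not be performed (insufficient background)."""


@dataclass
class HeightMap:
    """A 2D topograph: heights in nm on a square-pixel lattice.

    Row 0 is the top scan line; x increases with column index. ``frame``
    records whether the map is raw or has been background-flattened.
    """

    heights: np.ndarray
    pixel_size: float
    frame: str = "raw"
    source_id: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise FormatError("heights must be a 2D grid")
        if min(self.heights.shape) < MIN_GRID:
            raise FormatError(
                f"grid {self.heights.shape} smaller than {MIN_GRID}x{MIN_GRID}"
            )
        if not np.all(np.isfinite(self.heights)):
            raise DataError("non-finite height values")
        if not (self.pixel_size > 0):
            raise MetadataError("pixel_size must be > 0 nm/px")
        if self.frame not in ("raw", "flattened"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def with_heights(self, heights: np.ndarray, frame: Optional[str] = None) -> "HeightMap":
        return HeightMap(
            heights=heights,
            pixel_size=self.pixel_size,
            frame=self.frame if frame is None else frame,
            source_id=self.source_id,
        )


@dataclass
class BackgroundModel:
    """Per-row polynomial background removed by :func:`flatten`."""

    per_row_coefficients: np.ndarray  # (n_rows, order+1), lowest degree first
    background_mask: np.ndarray  # True where pixels were used for fitting
    rms_nm: float
    order: int = 3

    def to_json(self) -> str:
        return json.dumps(
            {
                "order": self.order,
                "rms_nm": self.rms_nm,
                "background_fraction": float(self.background_mask.mean()),
                "per_row_coefficients": self.per_row_coefficients.tolist(),
            }
        )


_PIXEL_SIZE_RE = re.compile(r"#\s*pixel_size_nm\s*=\s*([0-9.eE+-]+)")


def read_heightmap(path: str | Path, pixel_size: Optional[float] = None) -> HeightMap:
    """Read a height map from 32-bit float TIFF or a whitespace text grid.

    Text grids may carry an optional ``# pixel_size_nm=<v>`` header line;
    TIFFs may embed the pixel size in the ImageDescription as JSON. When no
    embedded value exists, ``pixel_size`` is mandatory.
    """
    path = Path(path)
    embedded: Optional[float] = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    embedded = float(meta.get("pixel_size_nm"))
                except (ValueError, TypeError, AttributeError):
                    embedded = None
        if arr.ndim != 2:
            raise FormatError(f"{path.name}: expected single-channel 2D image")
    else:
        rows: list[list[float]] = []
        for line in path.read_text().splitlines():
            m = _PIXEL_SIZE_RE.match(line)
            if m:
                embedded = float(m.group(1))
                continue
            if line.strip() == "" or line.lstrip().startswith("#"):
                continue
            rows.append([float(tok) for tok in line.split()])
        if not rows:
            raise FormatError(f"{path.name}: empty grid")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path.name}: ragged rows (widths {sorted(widths)})")
        arr = np.array(rows, dtype=np.float64)

    if not np.all(np.isfinite(arr)):
        raise DataError(f"{path.name}: non-finite height values")
    px = pixel_size if pixel_size is not None else embedded
    if px is None:
        raise MetadataError(f"{path.name}: pixel size not embedded and not supplied")
    return HeightMap(heights=np.asarray(arr, dtype=np.float64), pixel_size=float(px),
                     frame="raw", source_id=path.stem)


def write_heightmap(map: HeightMap, path: str | Path) -> Path:
    """Write a height map as 32-bit float TIFF or text grid (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        desc = json.dumps({"pixel_size_nm": map.pixel_size, "frame": map.frame})
        tifffile.imwrite(path, map.heights.astype(np.float32), description=desc)
    else:
        header = f"# pixel_size_nm={map.pixel_size:.17g}\n"
        body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in map.heights)
        path.write_text(header + body + "\n")
    return path


def _fit_rows(
    heights: np.ndarray, mask: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a per-row polynomial over masked (background) pixels.

    Returns (fitted surface, coefficient table). Column coordinate is scaled
    to [-1, 1] internally for conditioning; stored coefficients are in that
    scaled coordinate, lowest degree first.
    """
    n_rows, n_cols = heights.shape
    x = np.linspace(-1.0, 1.0, n_cols)
    fitted = np.empty_like(heights)
    coeffs = np.empty((n_rows, order + 1))
    for r in range(n_rows):
        sel = mask[r]
        n_bg = int(sel.sum())
        if n_bg < max(order + 1, int(np.ceil(MIN_BACKGROUND_FRACTION * n_cols))):
            raise FlattenError(
                f"row {r}: background mask covers {n_bg}/{n_cols} pixels "
                f"(< {MIN_BACKGROUND_FRACTION:.0%} or fewer than order+1)"
            )
        c = np.polynomial.polynomial.polyfit(x[sel], heights[r, sel], order)
        coeffs[r] = c
        fitted[r] = np.polynomial.polynomial.polyval(x, c)
    return fitted, coeffs


def flatten(
    map: HeightMap,
    order: int = 3,
    exclude_mask: Optional[np.ndarray] = None,
    object_threshold: float = 0.2,
) -> tuple[HeightMap, BackgroundModel]:
    """Remove the per-scan-row polynomial background of a raw topograph.

    When ``exclude_mask`` is given, those pixels are held out of every row
    fit. Otherwise two passes are made: a fit on all pixels, a provisional
    object mask at ``object_threshold`` nm on the residual, and a refit with
    objects excluded — fitting through tall molecules would otherwise pull
    the background up under them.

    The returned map is in the ``flattened`` frame: background mean ~0, so
    molecule heights read directly as heights above the film.
    """
    if map.frame != "raw" and exclude_mask is None:
        # flattening an already-flattened map must be a near no-op
        pass
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    h = map.heights
    if exclude_mask is not None:
        bg = ~np.asarray(exclude_mask, dtype=bool)
        fitted, coeffs = _fit_rows(h, bg, order)
    else:
        allpix = np.ones(h.shape, dtype=bool)
        fitted0, _ = _fit_rows(h, allpix, order)
        resid = h - fitted0
        bg = resid < object_threshold
        fitted, coeffs = _fit_rows(h, bg, order)
    flat = h - fitted
    # anchor the background mean at exactly zero
    flat = flat - flat[bg].mean()
    rms = float(np.sqrt(np.mean((flat[bg] - flat[bg].mean()) ** 2)))
    model = BackgroundModel(
        per_row_coefficients=coeffs, background_mask=bg, rms_nm=rms, order=order
    )
    return map.with_heights(flat, frame="flattened"), model


def rms_roughness(map: HeightMap, mask: Optional[np.ndarray] = None) -> float:
    """RMS of height deviations from the mean over ``mask`` (default: all pixels).

    The background-quality metric: ~0.3 nm on clean mica, ~0.6 nm on the
    film-like deposit that carries the molecules.
    """
    if map.frame != "flattened":
        raise ValueError("rms_roughness expects a flattened map")
    h = map.heights if mask is None else map.heights[np.asarray(mask, dtype=bool)]
    if h.size == 0:
        raise ValueError("empty mask")
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))
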