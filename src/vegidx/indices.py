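"""Per-pixel index mathematics.

NDVI is the normalized red/near-infrared difference

    NDVI = (NIR - RED) / (NIR + RED),

computed on the raw digital numbers (the common scale factor cancels)
and clamped to [-1, 1]; negative reflectances down to -100 are valid
inputs and are computed as-is before clamping.

The anomaly indices position the current composite NDVI against a
per-pixel historical reference for the same week-of-year:

    VCI   = (NDVI - NDVI_min) / (NDVI_max - NDVI_min)      in [0, 1]
    MVCI  = (NDVI - NDVI_mean)   / NDVI_mean               in [-1.25, 1.25]
    RMVCI = (NDVI - NDVI_median) / NDVI_median             in [-1.25, 1.25]
    RVCI  = (NDVI - NDVI_prev_year) / NDVI_prev_year       in [-1.25, 1.25]

The ratio indices are clamped at an absolute deviation of 125%,
mirroring the saturating product encoding.  Degenerate denominators
(max == min for VCI, a zero reference for the ratios) are masked rather
than forced to a value: no meaningful anomaly exists there.  Output
masks are always the union of the input masks plus those degenerate
cells.
"""

from __future__ import annotations

import numpy as np

from .errors import StructuralError
from .grids import GridGeometry, IndexGrid, IndexKind, ReflectanceScene

#: saturation bound on the deviation-ratio indices (125%)
RATIO_CLAMP = 1.25


def ndvi(scene: ReflectanceScene) -> IndexGrid:
    """Daily NDVI from a (validated) reflectance scene.

    Pixels that are invalid, or whose band sum is zero, are masked.
    """
    red = scene.red.astype(np.float64)
    nir = scene.nir.astype(np.float64)
    denom = nir + red
    mask = ~scene.valid | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (nir - red) / denom
    v = np.clip(v, -1.0, 1.0)
    v = np.where(mask, np.nan, v)
    return IndexGrid(values=v, nodata_mask=mask, kind=IndexKind.NDVI, geometry=scene.geometry)


def _check_coregistered(*grids: IndexGrid) -> GridGeometry:
    geom = grids[0].geometry
    for g in grids[1:]:
        if not geom.congruent(g.geometry):
            raise StructuralError("index grids are not co-registered")
    return geom


def vci(current: IndexGrid, hist_min: IndexGrid, hist_max: IndexGrid) -> IndexGrid:
    """Vegetation Condition Index: current NDVI within the historical envelope.

    Masked where any input is masked or the envelope is degenerate
    (max == min); clamped to [0, 1] (the current composite may exceed the
    archive extremes in near-real-time use).
    """
    geom = _check_coregistered(current, hist_min, hist_max)
    lo, hi, cur = hist_min.values, hist_max.values, current.values
    span = hi - lo
    mask = current.nodata_mask | hist_min.nodata_mask | hist_max.nodata_mask | (span == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (cur - lo) / span
    v = np.clip(v, 0.0, 1.0)
    v = np.where(mask, np.nan, v)
    return IndexGrid(values=v, nodata_mask=mask, kind=IndexKind.VCI,
                     geometry=geom, period=current.period)


def _deviation_ratio(current: IndexGrid, reference: IndexGrid, kind: IndexKind) -> IndexGrid:
    geom = _check_coregistered(current, reference)
    ref = reference.values
    mask = current.nodata_mask | reference.nodata_mask | (ref == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (current.values - ref) / ref
    v = np.clip(v, -RATIO_CLAMP, RATIO_CLAMP)
    v = np.where(mask, np.nan, v)
    return IndexGrid(values=v, nodata_mask=mask, kind=kind, geometry=geom, period=current.period)


def mvci(current: IndexGrid, hist_mean: IndexGrid) -> IndexGrid:
    """Relative deviation of current NDVI from the multi-year mean."""
    return _deviation_ratio(current, hist_mean, IndexKind.MVCI)


def rmvci(current: IndexGrid, hist_median: IndexGrid) -> IndexGrid:
    """Relative deviation of current NDVI from the multi-year median."""
    return _deviation_ratio(current, hist_median, IndexKind.RMVCI)


def rvci(current: IndexGrid, previous_year: IndexGrid) -> IndexGrid:
    """Relative deviation of current NDVI from the previous year's same-week NDVI."""
    return _deviation_ratio(current, previous_year, IndexKind.RVCI)


__all__ = ["ndvi", "vci", "mvci", "rmvci", "rvci", "RATIO_CLAMP"]
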