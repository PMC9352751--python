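"""Spatial mosaicking/clipping and temporal maximum-value compositing.

``mosaic_clip`` pastes same-day tiles sharing one pixel lattice onto the
union grid and clips it to an area of interest (a bounding box or a
shapely polygon).  Where tiles overlap, the first valid value in input
order wins — a deterministic rule chosen for testability.

``mvc`` is the maximum value composite: the per-pixel maximum of the
daily NDVI grids within a weekly or biweekly slot.  Picking the maximum
suppresses cloud-, fog- and no-data-depressed values in any single day;
a pixel stays masked only when every contributing day is masked.
Composites are computed on raw (unencoded) NDVI; encoding happens last.
A composite may be built from fewer days than the slot spans (mid-week
near-real-time use): ``n_days`` on the output records how many daily
grids contributed so callers can enforce a completeness policy.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import EmptyResultError, StructuralError
from .grids import GridGeometry, IndexGrid, IndexKind, ReflectanceScene
from .periods import CompositePeriod

try:  # shapely is used only for polygon AOIs
    import shapely
    from shapely.geometry.base import BaseGeometry
except Exception:  # pragma: no cover
    shapely = None
    BaseGeometry = ()


def _snap_offset(value: float, origin: float, pixel: float, what: str) -> int:
    off = (value - origin) / pixel
    snapped = round(off)
    if abs(off - snapped) > 1e-6:
        raise StructuralError(f"{what} is not aligned to the common pixel lattice")
    return int(snapped)


def mosaic_clip(
    tiles: list[ReflectanceScene],
    aoi: tuple[float, float, float, float] | "BaseGeometry | None" = None,
) -> ReflectanceScene:
    """Mosaic co-aligned same-day tiles and clip to an AOI.

    ``aoi`` is either ``(xmin, ymin, xmax, ymax)`` or a shapely geometry
    (pixels whose centers fall outside it are masked).  ``None`` keeps the
    full union footprint.
    """
    if not tiles:
        raise EmptyResultError("no tiles to mosaic")
    first = tiles[0]
    px = first.geometry.pixel_size
    for t in tiles[1:]:
        if t.date != first.date:
            raise StructuralError("tiles carry mixed dates")
        if t.geometry.crs_id != first.geometry.crs_id:
            raise StructuralError("tiles carry mixed CRSs")
        if abs(t.geometry.pixel_size - px) > 1e-9 * px:
            raise StructuralError("tiles carry mixed pixel sizes")

    # union footprint on the shared lattice
    xmin = min(t.geometry.origin_x for t in tiles)
    ymax = max(t.geometry.origin_y for t in tiles)
    xmax = max(t.geometry.bounds[2] for t in tiles)
    ymin = min(t.geometry.bounds[1] for t in tiles)

    poly = None
    if aoi is not None:
        if shapely is not None and isinstance(aoi, BaseGeometry):
            poly = aoi
            axmin, aymin, axmax, aymax = aoi.bounds
        else:
            axmin, aymin, axmax, aymax = aoi
        # shrink the union frame to the AOI bbox, snapped outward to the lattice
        xmin = xmin + math.floor(max(0.0, (axmin - xmin)) / px) * px
        xmax = xmax - math.floor(max(0.0, (xmax - axmax)) / px) * px
        ymax = ymax - math.floor(max(0.0, (ymax - aymax)) / px) * px
        ymin = ymin + math.floor(max(0.0, (aymin - ymin)) / px) * px
        if xmax <= xmin or ymax <= ymin:
            raise EmptyResultError("AOI does not intersect the mosaic footprint")

    n_cols = round((xmax - xmin) / px)
    n_rows = round((ymax - ymin) / px)
    geom = GridGeometry(n_rows, n_cols, xmin, ymax, px, first.geometry.crs_id)

    fill = np.int16(-32768)
    red = np.full(geom.shape, fill, dtype=np.int16)
    nir = np.full(geom.shape, fill, dtype=np.int16)
    valid = np.zeros(geom.shape, dtype=bool)

    for t in tiles:
        col0 = _snap_offset(t.geometry.origin_x, xmin, px, "tile origin x")
        row0 = _snap_offset(ymax, t.geometry.origin_y, px, "tile origin y")
        # overlap of this tile with the output frame
        r_lo, r_hi = max(0, row0), min(n_rows, row0 + t.geometry.n_rows)
        c_lo, c_hi = max(0, col0), min(n_cols, col0 + t.geometry.n_cols)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        tr = slice(r_lo - row0, r_hi - row0)
        tc = slice(c_lo - col0, c_hi - col0)
        out_r, out_c = slice(r_lo, r_hi), slice(c_lo, c_hi)
        # first valid value wins: write only where the output is still empty
        put = t.valid[tr, tc] & ~valid[out_r, out_c]
        red[out_r, out_c][put] = t.red[tr, tc][put]
        nir[out_r, out_c][put] = t.nir[tr, tc][put]
        valid[out_r, out_c] |= put

    if poly is not None:
        xs, ys = geom.pixel_centers()
        inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(geom.shape)
        valid &= inside

    return ReflectanceScene(red=red, nir=nir, valid=valid, date=first.date, geometry=geom)


def mvc(dailies: list[IndexGrid], period: CompositePeriod | None = None) -> IndexGrid:
    """Maximum value composite of daily NDVI grids.

    Per pixel, the maximum over the days where the pixel is valid; masked
    only where every day is masked.  ``period`` labels the output with the
    enclosing weekly/biweekly slot; ``n_days`` records how many dailies
    contributed (the completeness flag).
    """
    if not dailies:
        raise EmptyResultError("cannot composite an empty list of daily grids")
    geom = dailies[0].geometry
    for g in dailies:
        if g.kind is not IndexKind.NDVI:
            raise StructuralError(f"mvc composites NDVI grids, got {g.kind}")
        if not geom.congruent(g.geometry):
            raise StructuralError("daily grids are not co-registered")
    stack = np.stack([g.values for g in dailies])
    all_masked = np.all(np.stack([g.nodata_mask for g in dailies]), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels stay masked
        vals = np.where(all_masked, np.nan, np.nanmax(stack, axis=0))
    return IndexGrid(
        values=vals,
        nodata_mask=all_masked,
        kind=IndexKind.NDVI,
        geometry=geom,
        period=period,
        n_days=len(dailies),
    )


__all__ = ["mosaic_clip", "mvc"]
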