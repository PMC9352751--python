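"""Single-band GeoTIFF reading and writing.

Products are written as 8-bit unsigned single-band GeoTIFFs with the
no-data tag 255; input reflectance bands are read as 16-bit signed
integers (any other dtype is rejected).  Georeferencing travels in the
standard GeoTIFF tags — ModelPixelScale (33550), ModelTiepoint (33922)
and GDAL_NODATA (42113) — written and parsed directly through
``tifffile``.  The CRS is carried as an opaque text identifier in the
ImageDescription tag alongside the layer name; the tool is CRS-agnostic
and simply preserves whatever the inputs declare.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import tifffile

from .errors import ProductFormatError, StructuralError
from .grids import NODATA_BYTE, EncodedGrid, GridGeometry, IndexKind, ReflectanceScene
from .periods import KIND_ALIAS, CompositePeriod, layer_name, parse_layer_name

_SCENE_FILL = -32768  # masked reflectance cells (outside the valid range)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _geo_tags(geom: GridGeometry, nodata: int) -> list:
    px = float(geom.pixel_size)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(geom.origin_x), float(geom.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def _read_geometry(page: "tifffile.TiffPage", crs_id: str) -> GridGeometry:
    n_rows, n_cols = page.shape
    scale = page.tags.get(_TAG_PIXEL_SCALE)
    tie = page.tags.get(_TAG_TIEPOINT)
    if scale is None or tie is None:
        return GridGeometry(n_rows, n_cols, crs_id=crs_id)
    px = float(scale.value[0])
    # tiepoint maps raster (i, j) to map (x, y); we write it for the corner (0, 0)
    i, j, _, x, y, _ = (float(v) for v in tie.value[:6])
    return GridGeometry(n_rows, n_cols, x - i * px, y + j * px, px, crs_id)


def _description(parts: dict[str, str]) -> str:
    return "|".join(f"{k}={v}" for k, v in parts.items())


def _parse_description(text: str) -> dict[str, str]:
    out = {}
    for chunk in (text or "").split("|"):
        if "=" in chunk:
            k, _, v = chunk.partition("=")
            out[k] = v
    return out


def write_product(enc: EncodedGrid, path: str | Path) -> Path:
    """Write an encoded product grid as an 8-bit GeoTIFF with no-data 255."""
    path = Path(path)
    parts = {"kind": enc.kind.value, "crs": enc.geometry.crs_id}
    if isinstance(enc.period, CompositePeriod):
        parts["layer"] = layer_name(enc.kind, enc.period)
    tifffile.imwrite(
        path,
        enc.bytes,
        photometric="minisblack",
        description=_description(parts),
        extratags=_geo_tags(enc.geometry, NODATA_BYTE),
    )
    return path


def read_product(path: str | Path) -> EncodedGrid:
    """Read an encoded product GeoTIFF back; reserved bytes 251-254 are rejected."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if data.dtype != np.uint8:
            raise ProductFormatError(f"product raster must be uint8, got {data.dtype}")
        meta = _parse_description(page.description)
        geom = _read_geometry(page, meta.get("crs", "local"))
    bad = (data > 250) & (data != NODATA_BYTE)
    if bad.any():
        raise ProductFormatError(f"{int(bad.sum())} cells carry reserved bytes 251-254")
    kind = IndexKind(meta["kind"]) if "kind" in meta else IndexKind.NDVI
    period = None
    if "layer" in meta:
        parsed = parse_layer_name(meta["layer"])
        period = parsed.period
        if parsed.kind is not None:
            kind = parsed.kind
    return EncodedGrid(bytes=data, kind=kind, geometry=geom, period=period)


def _read_band(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        if data.dtype != np.int16:
            raise ProductFormatError(
                f"reflectance band {path} must be 16-bit signed integer, got {data.dtype}"
            )
        meta = _parse_description(page.description)
        geom = _read_geometry(page, meta.get("crs", "local"))
    return data, geom


def read_scene(red_path: str | Path, nir_path: str | Path, date: _dt.date) -> ReflectanceScene:
    """Read a co-registered RED/NIR GeoTIFF pair into a reflectance scene.

    The initial validity mask is all-true; out-of-range cells (including
    any fill value) are masked by ``validate_reflectance``.
    """
    red, rgeom = _read_band(red_path)
    nir, ngeom = _read_band(nir_path)
    if red.shape != nir.shape:
        raise StructuralError(f"band shapes differ: {red.shape} vs {nir.shape}")
    if not rgeom.congruent(ngeom):
        raise StructuralError("RED and NIR bands are not co-registered")
    valid = np.ones(red.shape, dtype=bool)
    return ReflectanceScene(red=red, nir=nir, valid=valid, date=date, geometry=rgeom)


def write_scene(scene: ReflectanceScene, red_path: str | Path, nir_path: str | Path) -> None:
    """Write a scene's bands as int16 GeoTIFFs; masked cells carry the fill value."""
    for band, path in ((scene.red, red_path), (scene.nir, nir_path)):
        out = np.array(band, dtype=np.int16, copy=True)
        out[~scene.valid] = _SCENE_FILL
        tifffile.imwrite(
            Path(path),
            out,
            photometric="minisblack",
            description=_description(
                {"crs": scene.geometry.crs_id, "date": scene.date.isoformat()}
            ),
            extratags=_geo_tags(scene.geometry, _SCENE_FILL),
        )


def write_float_grid(values: np.ndarray, geom: GridGeometry, path: str | Path) -> None:
    """Write a float32 raster (internal climatology archive, not a product)."""
    tifffile.imwrite(
        Path(path),
        values.astype(np.float32),
        photometric="minisblack",
        description=_description({"crs": geom.crs_id}),
        extratags=_geo_tags(geom, -9999),
    )


def read_float_grid(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(np.float64)
        meta = _parse_description(page.description)
        geom = _read_geometry(page, meta.get("crs", "local"))
    return data, geom


__all__ = [
    "write_product",
    "read_product",
    "read_scene",
    "write_scene",
    "write_float_grid",
    "read_float_grid",
]
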