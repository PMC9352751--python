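"""Scaled 8-bit encodings of the vegetation indices, and their inverses.

The product format stores every index as an unsigned byte in [0, 250]
with 255 as the no-data sentinel:

* NDVI in [-1, 1] maps affinely:   byte = round(v * 125 + 125)
* VCI in [0, 1] maps affinely:     byte = round(v * 250)
* MVCI/RMVCI/RVCI map piecewise, saturating at +/-125%::

      byte = 0                      if v <= -1.25
      byte = round(v * 100 + 125)   if -1.25 < v < 1.25
      byte = 250                    if v >= 1.25

Rounding is to the nearest integer with ties away from zero, so the
decoded center of each byte bin is unbiased; the source conventions do
not fix a rounding rule, and this one is documented prominently because
it is a deliberate choice.  Out-of-range values are clamped to the
index's nominal range *before* encoding (NDVI to [-1,1], VCI to [0,1]),
which keeps the scaled range exactly [0, 250].

Decoding inverts each affine map; for the ratio indices the saturated
bytes 0 and 250 decode to -1.25 and +1.25 (the original magnitude is not
recoverable).  Bytes 251-254 have no meaning and raise
:class:`~vegidx.errors.ProductFormatError`.
"""

from __future__ import annotations

import numpy as np

from .errors import EncodingError, ProductFormatError, StructuralError
from .grids import (
    NODATA_BYTE,
    REFLECTANCE_MAX,
    REFLECTANCE_MIN,
    EncodedGrid,
    IndexGrid,
    IndexKind,
    ReflectanceScene,
)


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Nearest integer, ties away from zero (np.round would round half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def validate_reflectance(scene: ReflectanceScene) -> ReflectanceScene:
    """Mask band values outside the MOD09GQ valid range [-100, 16000].

    The returned scene's mask is the input mask AND-ed with in-range
    checks on both bands; band values themselves are untouched, and a
    cell that is already invalid never becomes valid again.
    """
    in_range = (
        (scene.red >= REFLECTANCE_MIN)
        & (scene.red <= REFLECTANCE_MAX)
        & (scene.nir >= REFLECTANCE_MIN)
        & (scene.nir <= REFLECTANCE_MAX)
    )
    return ReflectanceScene(
        red=scene.red,
        nir=scene.nir,
        valid=scene.valid & in_range,
        date=scene.date,
        geometry=scene.geometry,
    )


def _check_finite(v: float) -> None:
    if not np.isfinite(v):
        raise EncodingError(f"cannot encode non-finite index value {v!r}")


def encode_ndvi(v: float) -> int:
    """NDVI float -> byte via round(v * 125 + 125); v clamped to [-1, 1] first."""
    _check_finite(v)
    v = min(1.0, max(-1.0, v))
    return int(_round_half_away(v * 125.0 + 125.0))


def encode_vci(v: float) -> int:
    """VCI float -> byte via round(v * 250); v clamped to [0, 1] first."""
    _check_finite(v)
    v = min(1.0, max(0.0, v))
    return int(_round_half_away(v * 250.0))


def encode_ratio(v: float) -> int:
    """MVCI/RMVCI/RVCI float -> byte, saturating at an absolute ratio of 125%."""
    _check_finite(v)
    if v <= -1.25:
        return 0
    if v >= 1.25:
        return 250
    return int(min(250.0, max(0.0, _round_half_away(v * 100.0 + 125.0))))


_ENCODERS = {
    IndexKind.NDVI: encode_ndvi,
    IndexKind.VCI: encode_vci,
    IndexKind.MVCI: encode_ratio,
    IndexKind.RMVCI: encode_ratio,
    IndexKind.RVCI: encode_ratio,
}


def encode_value(v: float, kind: IndexKind) -> int:
    """Dispatch to the kind's scalar encoder."""
    return _ENCODERS[kind](v)


def decode_value(byte: int, kind: IndexKind) -> float | None:
    """Byte -> index value; 255 -> None (no data); 251-254 -> error."""
    byte = int(byte)
    if byte == NODATA_BYTE:
        return None
    if not 0 <= byte <= 250:
        raise ProductFormatError(f"byte {byte} is outside the product alphabet 0..250, 255")
    if kind is IndexKind.NDVI:
        return (byte - 125) / 125.0
    if kind is IndexKind.VCI:
        return byte / 250.0
    # ratio kinds: affine inverse; 0 and 250 land exactly on the +/-1.25 saturation
    return (byte - 125) / 100.0


def encode_grid(g: IndexGrid) -> EncodedGrid:
    """Element-wise encoding of an index grid; masked cells become 255."""
    v = np.array(g.values, dtype=np.float64, copy=True)
    mask = g.nodata_mask | ~np.isfinite(v)
    v[mask] = 0.0  # placeholder, overwritten by the sentinel below
    if g.kind is IndexKind.NDVI:
        scaled = _round_half_away(np.clip(v, -1.0, 1.0) * 125.0 + 125.0)
    elif g.kind is IndexKind.VCI:
        scaled = _round_half_away(np.clip(v, 0.0, 1.0) * 250.0)
    else:
        scaled = _round_half_away(np.clip(v, -1.25, 1.25) * 100.0 + 125.0)
        scaled[v <= -1.25] = 0
        scaled[v >= 1.25] = 250
    scaled = np.clip(scaled, 0, 250).astype(np.uint8)
    scaled[mask] = NODATA_BYTE
    return EncodedGrid(bytes=scaled, kind=g.kind, geometry=g.geometry, period=g.period)


def decode_grid(e: EncodedGrid) -> IndexGrid:
    """Inverse of :func:`encode_grid`; 255 -> masked, 251-254 -> error."""
    b = np.asarray(e.bytes)
    bad = (b > 250) & (b != NODATA_BYTE)
    if bad.any():
        raise ProductFormatError(
            f"{int(bad.sum())} cells carry reserved bytes 251-254; product is corrupt"
        )
    mask = b == NODATA_BYTE
    bf = b.astype(np.float64)
    if e.kind is IndexKind.NDVI:
        vals = (bf - 125.0) / 125.0
    elif e.kind is IndexKind.VCI:
        vals = bf / 250.0
    else:
        vals = (bf - 125.0) / 100.0
    vals[mask] = np.nan
    return IndexGrid(
        values=vals, nodata_mask=mask, kind=e.kind, geometry=e.geometry, period=e.period
    )


__all__ = [
    "validate_reflectance",
    "encode_ndvi",
    "encode_vci",
    "encode_ratio",
    "encode_value",
    "decode_value",
    "encode_grid",
    "decode_grid",
]
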