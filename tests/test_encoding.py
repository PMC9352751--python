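"""Scaled 8-bit encodings, their inverses, and reflectance validation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vegidx import (
    EncodedGrid,
    GridGeometry,
    IndexGrid,
    IndexKind,
    ReflectanceScene,
    decode_grid,
    decode_value,
    encode_grid,
    encode_ndvi,
    encode_ratio,
    encode_value,
    encode_vci,
    validate_reflectance,
)
from vegidx.errors import EncodingError, ProductFormatError, StructuralError

# half of one quantization step per kind (decode error bound)
HALF_STEP = {IndexKind.NDVI: 1 / 250, IndexKind.VCI: 1 / 500, IndexKind.MVCI: 1 / 200}


@pytest.mark.parametrize(
    "fn,value,byte",
    [
        (encode_ndvi, 0.0, 125),
        (encode_ndvi, 1.0, 250),
        (encode_ndvi, -1.0, 0),
        (encode_ndvi, 0.5, 188),  # 187.5 rounds away from zero
        (encode_vci, 1.0, 250),
        (encode_vci, 0.0, 0),
        (encode_vci, 0.5, 125),
        (encode_ratio, -2.0, 0),
        (encode_ratio, 0.0, 125),
        (encode_ratio, 1.25, 250),
        (encode_ratio, -1.25, 0),
    ],
)
def test_scalar_encodings(fn, value, byte):
    assert fn(value) == byte


@pytest.mark.parametrize("fn", [encode_ndvi, encode_vci, encode_ratio])
@pytest.mark.parametrize("bad", [float("nan"), float("inf"), float("-inf")])
def test_nonfinite_rejected(fn, bad):
    with pytest.raises(EncodingError):
        fn(bad)


def test_out_of_range_clamped_before_encoding():
    assert encode_ndvi(1.7) == 250 and encode_ndvi(-3.0) == 0
    assert encode_vci(1.3) == 250 and encode_vci(-0.2) == 0


@pytest.mark.parametrize(
    "byte,kind,expected",
    [
        (125, IndexKind.NDVI, 0.0),
        (250, IndexKind.NDVI, 1.0),
        (0, IndexKind.VCI, 0.0),
        (250, IndexKind.MVCI, 1.25),  # saturated branch inverse
        (0, IndexKind.RVCI, -1.25),
    ],
)
def test_decode_examples(byte, kind, expected):
    assert decode_value(byte, kind) == pytest.approx(expected)


def test_decode_nodata_and_reserved_bytes():
    assert decode_value(255, IndexKind.NDVI) is None
    for b in (251, 252, 253, 254):
        with pytest.raises(ProductFormatError):
            decode_value(b, IndexKind.VCI)


@given(
    st.sampled_from(list(IndexKind)),
    st.floats(min_value=-3.0, max_value=3.0, allow_nan=False),
)
def test_encode_alphabet_and_roundtrip(kind, v):
    """Encoded bytes stay in {0..250}; decode∘encode is identity to half a step."""
    b = encode_value(v, kind)
    assert 0 <= b <= 250
    decoded = decode_value(b, kind)
    if kind is IndexKind.NDVI:
        clamped = min(1.0, max(-1.0, v))
    elif kind is IndexKind.VCI:
        clamped = min(1.0, max(0.0, v))
    else:
        clamped = min(1.25, max(-1.25, v))
    half = HALF_STEP[kind if not kind.is_ratio else IndexKind.MVCI]
    assert abs(decoded - clamped) <= half + 1e-12


@given(
    st.sampled_from(list(IndexKind)),
    st.floats(min_value=-2.0, max_value=2.0, allow_nan=False),
    st.floats(min_value=0.0, max_value=0.5, allow_nan=False),
)
def test_encode_monotone(kind, v, delta):
    assert encode_value(v + delta, kind) >= encode_value(v, kind)


def _scene(geom, red, nir, valid=None):
    valid = np.ones(geom.shape, bool) if valid is None else valid
    return ReflectanceScene(
        red=red, nir=nir, valid=valid, date=dt.date(2021, 6, 7), geometry=geom
    )


def test_validate_reflectance_bounds(geom8):
    red = np.zeros(geom8.shape, np.int16)
    nir = np.zeros(geom8.shape, np.int16)
    red[0, 0], nir[0, 0] = 0, 16000  # both at valid bounds
    red[0, 1] = 16001  # boundary + 1 excluded
    nir[0, 2] = -101
    out = validate_reflectance(_scene(geom8, red, nir))
    assert out.valid[0, 0]
    assert not out.valid[0, 1] and not out.valid[0, 2]
    assert (out.red == red).all() and (out.nir == nir).all()  # values untouched


def test_validate_never_unmasks(geom8, rng):
    red = rng.integers(-200, 17000, geom8.shape).astype(np.int16)
    nir = rng.integers(-200, 17000, geom8.shape).astype(np.int16)
    valid_in = rng.random(geom8.shape) > 0.5
    out = validate_reflectance(_scene(geom8, red, nir, valid_in))
    assert not (out.valid & ~valid_in).any()


def test_validate_shape_mismatch(geom8):
    with pytest.raises(StructuralError):
        ReflectanceScene(
            red=np.zeros((8, 8), np.int16),
            nir=np.zeros((8, 7), np.int16),
            valid=np.ones((8, 8), bool),
            date=dt.date(2021, 1, 1),
            geometry=geom8,
        )


def test_grid_encode_mask_and_values(geom8):
    vals = np.zeros(geom8.shape)
    mask = np.zeros(geom8.shape, bool)
    mask[3] = True
    g = IndexGrid(values=vals, nodata_mask=mask, kind=IndexKind.NDVI, geometry=geom8)
    enc = encode_grid(g)
    assert (enc.bytes[3] == 255).all()
    assert (enc.bytes[~mask] == 125).all()  # NDVI of 0 -> 125 everywhere valid
    all_masked = IndexGrid(
        values=vals, nodata_mask=np.ones(geom8.shape, bool), kind=IndexKind.VCI, geometry=geom8
    )
    assert (encode_grid(all_masked).bytes == 255).all()


@pytest.mark.parametrize("kind", list(IndexKind))
def test_grid_roundtrip_within_half_step(kind, geom8, rng):
    lo, hi = {
        IndexKind.NDVI: (-1, 1), IndexKind.VCI: (0, 1),
    }.get(kind, (-1.25, 1.25))
    vals = rng.uniform(lo, hi, geom8.shape)
    mask = rng.random(geom8.shape) > 0.8
    g = IndexGrid(values=vals, nodata_mask=mask, kind=kind, geometry=geom8)
    back = decode_grid(encode_grid(g))
    assert (back.nodata_mask == mask).all()
    half = HALF_STEP[kind if not kind.is_ratio else IndexKind.MVCI]
    assert np.nanmax(np.abs(back.values - np.where(mask, np.nan, vals))) <= half + 1e-12 or (
        np.isnan(back.values[~mask]).sum() == 0
    )
    assert np.all(np.abs(back.values[~mask] - vals[~mask]) <= half + 1e-12)


def test_decode_grid_rejects_reserved_bytes(geom8):
    b = np.full(geom8.shape, 125, np.uint8)
    b[0, 0] = 252
    with pytest.raises(ProductFormatError):
        decode_grid(EncodedGrid(bytes=b, kind=IndexKind.NDVI, geometry=geom8))
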