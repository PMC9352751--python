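"""Multi-year NDVI climatology: build/update equivalence and reference fields."""

import numpy as np
import pytest

from vegidx import GridGeometry, IndexGrid, IndexKind
from vegidx.climatology import (
    N_SLOTS,
    STATS,
    ClimatologyStack,
    build,
    previous_year,
    reference_for,
    update,
)
from vegidx.errors import EmptyReferenceError, PeriodLookupError, StructuralError

GEOM = GridGeometry(4, 4)


def _grid(values, mask=None):
    values = np.asarray(values, float)
    if values.shape != GEOM.shape:
        values = np.full(GEOM.shape, float(values))
    mask = np.zeros(GEOM.shape, bool) if mask is None else np.asarray(mask, bool)
    return IndexGrid(values=values, nodata_mask=mask, kind=IndexKind.NDVI, geometry=GEOM)


def test_single_year_all_stats_equal_the_grid():
    stack = build([(2020, 1, _grid(0.4))])
    for stat in STATS:
        np.testing.assert_array_equal(reference_for(stack, 1, stat).values, 0.4)


def test_hand_statistics_across_years():
    stack = build([(2018, 5, _grid(0.2)), (2019, 5, _grid(0.4)), (2020, 5, _grid(0.9))])
    expect = {"min": 0.2, "max": 0.9, "mean": 0.5, "median": 0.4}
    for stat, val in expect.items():
        np.testing.assert_allclose(reference_for(stack, 5, stat).values, val)


def test_median_even_count_mean_of_central_pair(rng):
    vals = [rng.uniform(0, 1, GEOM.shape) for _ in range(4)]
    stack = build([(2017 + i, 3, _grid(v)) for i, v in enumerate(vals)])
    med = reference_for(stack, 3, "median").values
    srt = np.sort(np.stack(vals), axis=0)  # independent sorting oracle
    np.testing.assert_allclose(med, (srt[1] + srt[2]) / 2)


def test_masked_everywhere_stays_masked():
    all_masked = _grid(0.0, mask=np.ones(GEOM.shape, bool))
    stack = build([(2020, 1, all_masked)])
    assert reference_for(stack, 1, "mean").nodata_mask.all()


def test_per_pixel_partial_masks():
    m1 = np.zeros(GEOM.shape, bool)
    m1[0, 0] = True
    stack = build([(2019, 1, _grid(0.2, mask=m1)), (2020, 1, _grid(0.8))])
    mx = reference_for(stack, 1, "max")
    assert mx.values[0, 0] == 0.8  # only 2020 contributes there
    assert mx.values[1, 1] == 0.8 and reference_for(stack, 1, "min").values[1, 1] == 0.2
    assert not mx.nodata_mask.any()


def test_update_equals_build_bitwise(rng):
    """Incremental insertion reproduces the batch build exactly."""
    years = range(2016, 2021)
    grids = {
        (y, w): _grid(rng.uniform(0, 1, GEOM.shape), mask=rng.random(GEOM.shape) > 0.9)
        for y in years
        for w in (1, 2)
    }
    batch = build([(y, w, g) for (y, w), g in grids.items()])
    inc = build([(y, w, g) for (y, w), g in grids.items() if y < 2020])
    for (y, w), g in grids.items():
        if y == 2020:
            update(inc, g, y, w)
    for w in (1, 2):
        for stat in STATS:
            a, b = reference_for(batch, w, stat), reference_for(inc, w, stat)
            np.testing.assert_array_equal(a.nodata_mask, b.nodata_mask)
            np.testing.assert_array_equal(
                np.nan_to_num(a.values, nan=-9), np.nan_to_num(b.values, nan=-9)
            )


def test_inserting_all_masked_year_leaves_derived_unchanged():
    stack = build([(2019, 1, _grid(0.3)), (2020, 1, _grid(0.7))])
    before = {s: reference_for(stack, 1, s).values.copy() for s in STATS}
    update(stack, _grid(0.0, mask=np.ones(GEOM.shape, bool)), 2021, 1)
    for s in STATS:
        np.testing.assert_array_equal(reference_for(stack, 1, s).values, before[s])


def test_replacing_a_year_matches_rebuild():
    stack = build([(2019, 1, _grid(0.3)), (2020, 1, _grid(0.7))])
    update(stack, _grid(0.5), 2020, 1)  # replace, logged
    fresh = build([(2019, 1, _grid(0.3)), (2020, 1, _grid(0.5))])
    for s in STATS:
        np.testing.assert_array_equal(
            reference_for(stack, 1, s).values, reference_for(fresh, 1, s).values
        )


def test_adding_a_year_only_widens_envelope(rng):
    stack = build([(2018 + i, 1, _grid(rng.uniform(0.2, 0.8, GEOM.shape))) for i in range(3)])
    lo0, hi0 = reference_for(stack, 1, "min").values, reference_for(stack, 1, "max").values
    update(stack, _grid(rng.uniform(0, 1, GEOM.shape)), 2021, 1)
    assert np.all(reference_for(stack, 1, "min").values <= lo0)
    assert np.all(reference_for(stack, 1, "max").values >= hi0)


def test_order_statistics_bracket_mean_and_median(rng):
    stack = build([(2016 + i, 1, _grid(rng.uniform(0, 1, GEOM.shape))) for i in range(5)])
    lo = reference_for(stack, 1, "min").values
    hi = reference_for(stack, 1, "max").values
    for stat in ("mean", "median"):
        mid = reference_for(stack, 1, stat).values
        assert np.all(lo <= mid + 1e-12) and np.all(mid <= hi + 1e-12)


def test_reference_policy_excludes_current_year():
    stack = build([(2019, 1, _grid(0.2)), (2020, 1, _grid(0.4)), (2021, 1, _grid(0.9))])
    excl = reference_for(stack, 1, "max", current_year=2021)
    incl = reference_for(stack, 1, "max", current_year=2021, include_current=True)
    np.testing.assert_allclose(excl.values, 0.4)
    np.testing.assert_allclose(incl.values, 0.9)
    with pytest.raises(EmptyReferenceError):
        reference_for(stack, 1, "min", current_year=2019)


def test_week_slots_fixed_at_53():
    stack = ClimatologyStack(geometry=GEOM)
    assert list(stack.week_slots) == list(range(1, 54))
    assert N_SLOTS == 53
    with pytest.raises(StructuralError):
        stack.insert(_grid(0.5), 2020, 54)


def test_previous_year_lookup_and_week53_fallback():
    stack = build([(2020, 23, _grid(0.6)), (2020, 52, _grid(0.3))])
    assert previous_year(stack, 2021, 23).values[0, 0] == 0.6
    # 2020 has 53 ISO weeks; 2021 has 52 -> asking week 53 of 2022 falls back to 52 of 2021
    stack2 = build([(2021, 52, _grid(0.45))])
    fallback = previous_year(stack2, 2022, 53)
    assert fallback.values[0, 0] == 0.45
    with pytest.raises(PeriodLookupError):
        previous_year(stack, 2020, 23)
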