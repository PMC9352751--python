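"""Multi-year per-pixel NDVI climatology.

The archive keeps, for every week-of-year slot 1..53, the weekly (or
biweekly) NDVI composite of each archived year, and derives from those
the per-pixel reference fields MIN / MAX / MEAN / MEDIAN that feed the
anomaly indices.  All 53 slots exist regardless of whether a given year
has 52 or 53 weeks, so the set of reference layers is fixed.

Per-year grids are retained in full: the median (and exact min/max under
replacement) cannot be maintained from running sums, and keeping the
grids makes the incremental ``update`` path provably identical to a full
rebuild — derived fields are always recomputed from the stored grids, so
``update(build(Y1..Yn-1), Yn)`` equals ``build(Y1..Yn)`` bitwise.

Median over an even number of years is the mean of the two central
values.  A pixel is masked in a derived field only when it is masked in
every contributing year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyReferenceError, PeriodLookupError, StructuralError
from .grids import GridGeometry, IndexGrid, IndexKind
from .periods import WEEKLY, iso_weeks_in_year

logger = logging.getLogger(__name__)

#: fixed number of week-of-year slots in the archive
N_SLOTS = 53

STATS = ("min", "max", "mean", "median")

_REDUCERS = {
    "min": np.nanmin,
    "max": np.nanmax,
    "mean": np.nanmean,
    "median": np.nanmedian,
}


@dataclass
class ClimatologyStack:
    """Per-week-of-year archive of yearly NDVI composites plus derived fields."""

    geometry: GridGeometry
    cadence: str = WEEKLY
    #: week slot -> {year -> IndexGrid[NDVI]}
    weeks: dict[int, dict[int, IndexGrid]] = field(default_factory=dict)
    _derived_cache: dict = field(default_factory=dict, repr=False)

    @property
    def week_slots(self) -> range:
        return range(1, N_SLOTS + 1)

    def years(self, week: int) -> list[int]:
        return sorted(self.weeks.get(week, {}))

    def all_years(self) -> list[int]:
        ys: set[int] = set()
        for per_year in self.weeks.values():
            ys.update(per_year)
        return sorted(ys)

    def insert(self, grid: IndexGrid, year: int, week: int) -> None:
        """Insert (or replace, logged) one year's composite for a week slot."""
        if grid.kind is not IndexKind.NDVI:
            raise StructuralError(f"climatology stores NDVI composites, got {grid.kind}")
        if not self.geometry.congruent(grid.geometry):
            raise StructuralError("composite geometry does not match the stack")
        if not 1 <= week <= N_SLOTS:
            raise StructuralError(f"week slot {week} outside 1..{N_SLOTS}")
        slot = self.weeks.setdefault(week, {})
        if year in slot:
            logger.info("replacing existing composite for year %d week %d", year, week)
        slot[year] = grid
        self._derived_cache.clear()

    def _derive(self, week: int, stat: str, years: tuple[int, ...]) -> IndexGrid:
        key = (week, stat, years)
        if key in self._derived_cache:
            return self._derived_cache[key]
        grids = [self.weeks[week][y] for y in years]
        stack = np.stack([g.values for g in grids])
        all_masked = np.all(np.stack([g.nodata_mask for g in grids]), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels stay masked
            vals = _REDUCERS[stat](stack, axis=0)
        vals = np.where(all_masked, np.nan, vals)
        out = IndexGrid(
            values=vals, nodata_mask=all_masked, kind=IndexKind.NDVI, geometry=self.geometry
        )
        self._derived_cache[key] = out
        return out

    def derived(self, week: int, stat: str) -> IndexGrid:
        """Reference field over *all* archived years for a week slot."""
        return reference_for(self, week, stat)


def build(
    composites: list[tuple[int, int, IndexGrid]],
    geometry: GridGeometry | None = None,
    cadence: str = WEEKLY,
) -> ClimatologyStack:
    """Build a stack from ``(year, week, composite)`` triples."""
    if not composites and geometry is None:
        raise StructuralError("cannot infer geometry from an empty archive")
    geom = geometry if geometry is not None else composites[0][2].geometry
    stack = ClimatologyStack(geometry=geom, cadence=cadence)
    for year, week, grid in composites:
        stack.insert(grid, year, week)
    return stack


def update(stack: ClimatologyStack, grid: IndexGrid, year: int, week: int) -> ClimatologyStack:
    """Insert a new yearly composite; derived fields match a full rebuild."""
    stack.insert(grid, year, week)
    return stack


def reference_for(
    stack: ClimatologyStack,
    week: int,
    stat: str,
    *,
    current_year: int | None = None,
    include_current: bool = False,
) -> IndexGrid:
    """Derived reference field for a week slot under a reference policy.

    By default all archived years contribute; passing ``current_year``
    restricts to years strictly before it unless ``include_current`` is
    set (the in-progress year damps its own anomaly if included).
    """
    if stat not in STATS:
        raise StructuralError(f"unknown statistic {stat!r}; expected one of {STATS}")
    if not 1 <= week <= N_SLOTS:
        raise StructuralError(f"week slot {week} outside 1..{N_SLOTS}")
    years = stack.years(week)
    if current_year is not None and not include_current:
        years = [y for y in years if y < current_year]
    if not years:
        raise EmptyReferenceError(
            f"no archived years for week {week} under the given reference policy"
        )
    return stack._derive(week, stat, tuple(years))


def previous_year(stack: ClimatologyStack, year: int, week: int) -> IndexGrid:
    """The previous year's composite for the same week slot.

    When asking for week 53 of a year whose predecessor has only 52 ISO
    weeks, falls back to the predecessor's week 52 (logged).
    """
    slot = stack.weeks.get(week, {})
    if year - 1 in slot:
        return slot[year - 1]
    if week == 53 and iso_weeks_in_year(year - 1) == 52:
        fallback = stack.weeks.get(52, {})
        if year - 1 in fallback:
            logger.info("week 53 of %d: falling back to week 52 of %d", year, year - 1)
            return fallback[year - 1]
    raise PeriodLookupError(f"no archived composite for year {year - 1}, week {week}")


__all__ = [
    "ClimatologyStack",
    "N_SLOTS",
    "STATS",
    "build",
    "update",
    "reference_for",
    "previous_year",
]
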