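"""Temporal partitioning and the product naming convention.

Weekly products follow the ISO-8601 week calendar (weeks start on
Monday; a year has 52 or 53 weeks, and dates near the year boundary
belong to their ISO year).  Biweekly products pair consecutive ISO weeks
(1,2), (3,4), ...; when a year has 53 weeks the orphan week 53 forms a
short final 7-day period.  Daily products are grouped by calendar year.

Layer names follow the operational WMS/WCS convention, e.g.::

    NDVI-WEEKLY_2021_01_2021.01.04_2021.01.10
    NDVI-DAILY_2021.01.01
    NDVI-MULTIYEAR-WEEKLY_01_MEAN

with the historical aliases RVCI -> "RNDVI" and RMVCI -> "RMNDVI".
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

from .errors import ProductFormatError, StructuralError
from .grids import IndexKind

DAILY = "daily"
WEEKLY = "weekly"
BIWEEKLY = "biweekly"

_SPANS = {DAILY: 1, WEEKLY: 7, BIWEEKLY: 14}


@dataclass(frozen=True, order=True)
class CompositePeriod:
    """One daily/weekly/biweekly slot: (year, week, start..end, cadence).

    For daily cadence ``week`` holds the day-of-year instead of a week
    number.  ``end`` is inclusive.
    """

    year: int
    week: int
    start: _dt.date
    end: _dt.date
    cadence: str = WEEKLY

    def __post_init__(self) -> None:
        if self.cadence not in _SPANS:
            raise StructuralError(f"unknown cadence {self.cadence!r}")
        span = (self.end - self.start).days + 1
        if self.end < self.start:
            raise StructuralError("period end precedes start")
        if self.cadence == DAILY and span != 1:
            raise StructuralError("daily period must span one day")
        if self.cadence == WEEKLY and span != 7:
            raise StructuralError("weekly period must span 7 days")
        if self.cadence == BIWEEKLY and span not in (7, 14):
            # 7 only for the orphan-week-53 tail of a 53-week year
            raise StructuralError("biweekly period must span 14 days (7 for the orphan tail)")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def __contains__(self, d: _dt.date) -> bool:
        return self.start <= d <= self.end


def iso_weeks_in_year(year: int) -> int:
    """52 or 53, per the ISO-8601 week calendar."""
    return _dt.date(year, 12, 28).isocalendar()[1]


def week_of(d: _dt.date) -> tuple[int, int]:
    """ISO (year, week) of a date; 2021-01-01 belongs to (2020, 53)."""
    iso = d.isocalendar()
    return (iso[0], iso[1])


def week_period(year: int, week: int) -> CompositePeriod:
    """The 7-day weekly slot for ISO (year, week)."""
    start = _dt.date.fromisocalendar(year, week, 1)
    return CompositePeriod(year, week, start, start + _dt.timedelta(days=6), WEEKLY)


def week_partition(year: int) -> list[CompositePeriod]:
    """All ISO weeks of a year, in order (length 52 or 53)."""
    return [week_period(year, w) for w in range(1, iso_weeks_in_year(year) + 1)]


def biweekly_partition(year: int) -> list[CompositePeriod]:
    """Consecutive ISO-week pairs; an unpaired week 53 ends the list as 7 days."""
    n = iso_weeks_in_year(year)
    out = []
    k = 0
    for w in range(1, n + 1, 2):
        k += 1
        start = _dt.date.fromisocalendar(year, w, 1)
        last_week = min(w + 1, n)
        end = _dt.date.fromisocalendar(year, last_week, 7)
        out.append(CompositePeriod(year, k, start, end, BIWEEKLY))
    return out


def biweekly_period(year: int, k: int) -> CompositePeriod:
    """Biweekly slot k (1-based): spans ISO weeks 2k-1..2k."""
    return biweekly_partition(year)[k - 1]


def daily_partition(year: int) -> list[CompositePeriod]:
    """One period per calendar day of the year (365 or 366)."""
    d = _dt.date(year, 1, 1)
    out = []
    while d.year == year:
        doy = d.timetuple().tm_yday
        out.append(CompositePeriod(year, doy, d, d, DAILY))
        d += _dt.timedelta(days=1)
    return out


def period_for(d: _dt.date, cadence: str) -> CompositePeriod:
    """The weekly/biweekly/daily slot containing a date."""
    if cadence == DAILY:
        return CompositePeriod(d.year, d.timetuple().tm_yday, d, d, DAILY)
    y, w = week_of(d)
    if cadence == WEEKLY:
        return week_period(y, w)
    return biweekly_period(y, (w + 1) // 2)


# --- naming convention ------------------------------------------------------

#: operational layer-name aliases (the ratio-to-NDVI indices keep legacy names)
KIND_ALIAS = {
    IndexKind.NDVI: "NDVI",
    IndexKind.VCI: "VCI",
    IndexKind.MVCI: "MVCI",
    IndexKind.RMVCI: "RMNDVI",
    IndexKind.RVCI: "RNDVI",
}
_ALIAS_KIND = {v: k for k, v in KIND_ALIAS.items()}

MULTIYEAR_METHODS = ("MIN", "MAX", "MEAN", "MEDIAN")


def _fmt(d: _dt.date) -> str:
    return d.strftime("%Y.%m.%d")


def layer_name(kind: IndexKind, period: CompositePeriod) -> str:
    """Layer name of a dated product, e.g. ``VCI-WEEKLY_2021_01_2021.01.04_2021.01.10``."""
    alias = KIND_ALIAS[kind]
    if period.cadence == DAILY:
        return f"{alias}-DAILY_{_fmt(period.start)}"
    return (
        f"{alias}-{period.cadence.upper()}_{period.year}_{period.week:02d}"
        f"_{_fmt(period.start)}_{_fmt(period.end)}"
    )


def multiyear_layer_name(cadence: str, week: int, method: str) -> str:
    """Layer name of a multi-year NDVI reference field, e.g. ``NDVI-MULTIYEAR-WEEKLY_01_MEAN``."""
    method = method.upper()
    if method not in MULTIYEAR_METHODS:
        raise ProductFormatError(f"unknown multi-year method {method!r}")
    if cadence not in (WEEKLY, BIWEEKLY):
        raise ProductFormatError(f"multi-year layers exist for weekly/biweekly only, not {cadence!r}")
    return f"NDVI-MULTIYEAR-{cadence.upper()}_{week:02d}_{method}"


@dataclass(frozen=True)
class ParsedLayerName:
    """Components recovered from a layer-name string."""

    kind: IndexKind | None  # None for multi-year reference layers (always NDVI-derived)
    cadence: str
    period: CompositePeriod | None
    week: int | None = None  # multi-year layers only
    method: str | None = None  # multi-year layers only


_DATE_RE = r"(\d{4})\.(\d{2})\.(\d{2})"
_ALIASES = "|".join(sorted(_ALIAS_KIND, key=len, reverse=True))
_DAILY_RE = re.compile(rf"^({_ALIASES})-DAILY_{_DATE_RE}$")
_DATED_RE = re.compile(
    rf"^({_ALIASES})-(WEEKLY|BIWEEKLY)_(\d{{4}})_(\d{{2}})_{_DATE_RE}_{_DATE_RE}$"
)
_MULTI_RE = re.compile(r"^NDVI-MULTIYEAR-(WEEKLY|BIWEEKLY)_(\d{2})_(MIN|MAX|MEAN|MEDIAN)$")


def parse_layer_name(text: str) -> ParsedLayerName:
    """Exact inverse of :func:`layer_name` / :func:`multiyear_layer_name`."""
    m = _MULTI_RE.match(text)
    if m:
        return ParsedLayerName(
            kind=None, cadence=m.group(1).lower(), period=None,
            week=int(m.group(2)), method=m.group(3),
        )
    m = _DAILY_RE.match(text)
    if m:
        d = _dt.date(int(m.group(2)), int(m.group(3)), int(m.group(4)))
        return ParsedLayerName(
            kind=_ALIAS_KIND[m.group(1)], cadence=DAILY,
            period=CompositePeriod(d.year, d.timetuple().tm_yday, d, d, DAILY),
        )
    m = _DATED_RE.match(text)
    if m:
        alias, cad, year, week = m.group(1), m.group(2).lower(), int(m.group(3)), int(m.group(4))
        start = _dt.date(int(m.group(5)), int(m.group(6)), int(m.group(7)))
        end = _dt.date(int(m.group(8)), int(m.group(9)), int(m.group(10)))
        try:
            period = CompositePeriod(year, week, start, end, cad)
        except StructuralError as exc:
            raise ProductFormatError(f"inconsistent dates in layer name {text!r}: {exc}") from exc
        return ParsedLayerName(kind=_ALIAS_KIND[alias], cadence=cad, period=period)
    raise ProductFormatError(f"layer name {text!r} does not match the naming convention")


__all__ = [
    "DAILY",
    "WEEKLY",
    "BIWEEKLY",
    "CompositePeriod",
    "iso_weeks_in_year",
    "week_of",
    "week_period",
    "week_partition",
    "biweekly_partition",
    "biweekly_period",
    "daily_partition",
    "period_for",
    "KIND_ALIAS",
    "MULTIYEAR_METHODS",
    "layer_name",
    "multiyear_layer_name",
    "ParsedLayerName",
    "parse_layer_name",
]
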