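"""Synthetic MOD09GQ-like scenes with known ground truth.

The generator emulates the statistical shape of a surface-reflectance
archive well enough to exercise every pipeline stage without downloads:

* a seasonal true-NDVI curve per pixel,
  ``base + amp * sin(2*pi*(doy - phase)/365)``, with the vegetated
  default range 0.2..0.8;
* a fixed east-west spatial gradient (fields are not spatially flat);
* a deterministic per-year level offset (evenly spread, order shuffled
  by seed) standing in for inter-annual variability — without it every
  year repeats identically and the historical min/max envelope
  degenerates, leaving VCI undefined;
* per-pixel Gaussian observation noise; and
* contiguous random cloud blobs that mask a requested fraction of the
  scene.

Truth grids invert exactly to integer reflectance pairs, so a round
trip through the NDVI equation reproduces the truth to within
``1/total_dn``.  Everything is seed-parameterized and regenerates
byte-identically; per-date random streams are derived from
``(seed, ordinal date)`` so a grid does not depend on generation order.

What the generator does *not* emulate: radiative-transfer or BRDF
effects, sensor geometry, spatially correlated noise, snow, or the
MODIS sinusoidal tiling.  Pipeline tests passing on these fields show
the *bookkeeping* (masks, composites, climatology, encodings) is right,
not that real-scene retrievals are accurate.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import StructuralError, VegidxError
from .grids import GridGeometry, ReflectanceScene
from .periods import week_partition

#: default digital-number band sum; NDVI inversion error is <= 1/total_dn
DEFAULT_TOTAL_DN = 8000

#: default raster edge — a 3-year weekly archive at this size builds in seconds
DEFAULT_SIZE = 128


@dataclass(frozen=True)
class SeasonalParams:
    """Parameters of the synthetic true-NDVI field.

    base
        mean NDVI level; the vegetated range is roughly 0.2..0.8.
    amplitude
        seasonal half-range; base +/- amplitude spans spring trough to
        summer peak.
    phase_doy
        day-of-year of the ascending zero crossing; the seasonal peak
        falls a quarter period (~91 days) later.
    noise_sd
        per-pixel, per-day Gaussian observation noise (NDVI units).
    gradient
        total east-west NDVI difference across the raster, applied as a
        linear ramp centered on zero.
    interannual_sd
        half-range of the deterministic per-year level offsets; offsets
        are evenly spread over [-interannual_sd, +interannual_sd] and
        assigned to years in a seed-shuffled order.
    """

    base: float = 0.5
    amplitude: float = 0.3
    phase_doy: float = 109.0
    noise_sd: float = 0.02
    gradient: float = 0.1
    interannual_sd: float = 0.08

    def __post_init__(self) -> None:
        if not 0.2 <= self.base <= 0.8:
            raise VegidxError(f"base NDVI {self.base} outside the vegetated range 0.2..0.8")
        reach = abs(self.amplitude) + abs(self.gradient) / 2 + abs(self.interannual_sd)
        if self.base + reach > 1.0 or self.base - reach < -1.0:
            raise VegidxError("seasonal parameters can leave the NDVI range [-1, 1]")


def _date_rng(seed: int, d: _dt.date, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, d.toordinal(), stream])


def year_offsets(years: list[int], seed: int, params: SeasonalParams) -> dict[int, float]:
    """Deterministic per-year NDVI level offsets, evenly spread and seed-shuffled."""
    n = len(years)
    if n == 1:
        return {years[0]: 0.0}
    spread = np.linspace(-params.interannual_sd, params.interannual_sd, n)
    order = np.random.default_rng([seed, 911]).permutation(n)
    return {y: float(spread[order[i]]) for i, y in enumerate(sorted(years))}


def true_ndvi(
    n_rows: int,
    n_cols: int,
    d: _dt.date,
    seed: int,
    params: SeasonalParams = SeasonalParams(),
    year_offset: float = 0.0,
    with_noise: bool = True,
) -> np.ndarray:
    """True NDVI field for one date (noise-free if ``with_noise`` is False)."""
    doy = d.timetuple().tm_yday
    seasonal = params.base + params.amplitude * np.sin(
        2.0 * np.pi * (doy - params.phase_doy) / 365.0
    )
    ramp = np.linspace(-params.gradient / 2, params.gradient / 2, n_cols)
    field = seasonal + year_offset + np.tile(ramp, (n_rows, 1))
    if with_noise and params.noise_sd > 0:
        field = field + _date_rng(seed, d).normal(0.0, params.noise_sd, (n_rows, n_cols))
    return np.clip(field, -1.0, 1.0)


def make_truth_series(
    n_rows: int,
    n_cols: int,
    years: list[int],
    seed: int,
    params: SeasonalParams = SeasonalParams(),
    with_noise: bool = True,
) -> list[tuple[_dt.date, np.ndarray]]:
    """Daily true-NDVI grids covering the ISO weeks of each requested year.

    Dates span the first Monday through the last Sunday of each year's
    ISO week calendar, so weekly composites built from the series are
    complete.  Deterministic given ``seed``.
    """
    offsets = year_offsets(list(years), seed, params)
    out: list[tuple[_dt.date, np.ndarray]] = []
    for year in years:
        weeks = week_partition(year)
        d = weeks[0].start
        while d <= weeks[-1].end:
            out.append(
                (d, true_ndvi(n_rows, n_cols, d, seed, params, offsets[year], with_noise))
            )
            d += _dt.timedelta(days=1)
    return out


def to_reflectance(
    truth: np.ndarray,
    d: _dt.date,
    geometry: GridGeometry | None = None,
    total_dn: int = DEFAULT_TOTAL_DN,
) -> ReflectanceScene:
    """Invert NDVI to an integer RED/NIR pair with band sum ``total_dn``.

    ``ndvi(to_reflectance(v))`` reproduces ``v`` to within ``1/total_dn``.
    """
    if not 0 < total_dn <= 32000:
        raise VegidxError(f"total_dn must be in (0, 32000], got {total_dn}")
    if geometry is None:
        geometry = GridGeometry(*truth.shape)
    elif geometry.shape != truth.shape:
        raise StructuralError("geometry shape does not match the truth grid")
    nir = np.rint(total_dn * (1.0 + truth) / 2.0).astype(np.int16)
    red = np.rint(total_dn * (1.0 - truth) / 2.0).astype(np.int16)
    return ReflectanceScene(
        red=red, nir=nir, valid=np.ones(truth.shape, dtype=bool), date=d, geometry=geometry
    )


def add_clouds(scene: ReflectanceScene, cover_fraction: float, seed: int) -> ReflectanceScene:
    """Mask contiguous random blobs covering ``cover_fraction`` of the scene.

    A Gaussian-smoothed noise field is thresholded at the requested
    quantile, which yields spatially contiguous blobs and pins the
    masked fraction to the request (well inside +/-0.05).  Deterministic
    given ``seed`` and the scene date.
    """
    if not 0.0 <= cover_fraction <= 1.0:
        raise VegidxError(f"cover_fraction must be in [0, 1], got {cover_fraction}")
    if cover_fraction == 0.0:
        return scene
    valid = scene.valid.copy()
    if cover_fraction == 1.0:
        valid[:] = False
    else:
        rng = _date_rng(seed, scene.date, stream=1)
        noise = rng.standard_normal(scene.geometry.shape)
        sigma = max(2.0, min(scene.geometry.shape) / 16.0)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma)
        cutoff = np.quantile(smooth, cover_fraction)
        valid &= smooth > cutoff
    return ReflectanceScene(
        red=scene.red, nir=scene.nir, valid=valid, date=scene.date, geometry=scene.geometry
    )


__all__ = [
    "SeasonalParams",
    "DEFAULT_TOTAL_DN",
    "DEFAULT_SIZE",
    "year_offsets",
    "true_ndvi",
    "make_truth_series",
    "to_reflectance",
    "add_clouds",
]
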