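"""End-to-end product pipeline: validate -> mosaic/clip -> NDVI -> MVC ->
climatology update -> derived indices -> encode -> write.

Driven by a declarative config (a plain dict, typically loaded from a
YAML file; every CLI flag overrides a config key).  Re-runs are
idempotent: a product whose output file already exists is skipped
unless ``overwrite`` is set, and the structured log records per-stage
pixel counts (valid / masked / written / skipped) so mask bookkeeping
is observable.

A failure to derive one product for one period (for example RVCI in the
archive's first year, where no previous year exists) is recorded and
does not abort the other products.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import climatology as clim
from . import compositing, encoding, indices, periods, synth
from .errors import EmptyReferenceError, PeriodLookupError, VegidxError
from .geotiff import (
    read_float_grid,
    read_scene,
    write_float_grid,
    write_product,
)
from .grids import GridGeometry, IndexGrid, IndexKind, ReflectanceScene
from .periods import BIWEEKLY, WEEKLY, CompositePeriod

logger = logging.getLogger(__name__)

_ARCHIVE_SUFFIX = ".f32.tif"


@dataclass
class PipelineResult:
    """What a run produced: paths written, paths skipped, per-product errors."""

    written: list[Path] = field(default_factory=list)
    skipped: list[Path] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)
    composites: dict[tuple[int, int], IndexGrid] = field(default_factory=dict)
    stack: clim.ClimatologyStack | None = None

    def log(self, stage: str, **counts) -> None:
        entry = {"stage": stage, **counts}
        self.stage_log.append(entry)
        logger.info("%s: %s", stage, counts)


def _load_aoi(spec):
    """AOI from a bbox sequence or a GeoJSON file/geometry mapping."""
    if spec is None:
        return None
    if isinstance(spec, (list, tuple)) and len(spec) == 4:
        return tuple(float(v) for v in spec)
    import shapely.geometry

    if isinstance(spec, (str, Path)):
        payload = json.loads(Path(spec).read_text())
    else:
        payload = spec
    if payload.get("type") == "FeatureCollection":
        payload = payload["features"][0]["geometry"]
    elif payload.get("type") == "Feature":
        payload = payload["geometry"]
    return shapely.geometry.shape(payload)


def _synth_scenes(cfg: dict, seed: int) -> list[ReflectanceScene]:
    params = synth.SeasonalParams(**cfg.get("params", {}))
    n_rows = int(cfg.get("n_rows", synth.DEFAULT_SIZE))
    n_cols = int(cfg.get("n_cols", synth.DEFAULT_SIZE))
    years = [int(y) for y in cfg["years"]]
    total_dn = int(cfg.get("total_dn", synth.DEFAULT_TOTAL_DN))
    cloud = float(cfg.get("cloud_fraction", 0.0))
    # unit pixels with the top-left corner at (0, n_rows): map y increases upward
    geom = GridGeometry(n_rows, n_cols, 0.0, float(n_rows), 1.0, str(cfg.get("crs", "local")))
    truths = synth.make_truth_series(n_rows, n_cols, years, seed, params)
    scenes = []
    for d, t in truths:
        scene = synth.to_reflectance(t, d, geom, total_dn)
        if cloud > 0:
            scene = synth.add_clouds(scene, cloud, seed)
        scenes.append(scene)
    return scenes


def _collect_scenes(config: dict, result: PipelineResult) -> list[ReflectanceScene]:
    source = config.get("input", {})
    if "synth" in source:
        scenes = _synth_scenes(source["synth"], int(config.get("seed", 0)))
    elif "scenes" in source:
        scenes = []
        for item in source["scenes"]:
            date = _dt.date.fromisoformat(str(item["date"]))
            scenes.append(read_scene(item["red"], item["nir"], date))
    else:
        raise VegidxError("config.input must provide either 'synth' or 'scenes'")
    result.log("ingest", scenes=len(scenes))
    return scenes


def _daily_ndvi(scenes: list[ReflectanceScene], aoi, result: PipelineResult) -> list[IndexGrid]:
    by_date: dict[_dt.date, list[ReflectanceScene]] = {}
    for s in scenes:
        by_date.setdefault(s.date, []).append(s)
    dailies = []
    n_valid = n_masked = 0
    for d in sorted(by_date):
        tiles = by_date[d]
        scene = tiles[0] if len(tiles) == 1 and aoi is None else compositing.mosaic_clip(tiles, aoi)
        scene = encoding.validate_reflectance(scene)
        grid = indices.ndvi(scene)
        n_valid += int((~grid.nodata_mask).sum())
        n_masked += int(grid.nodata_mask.sum())
        dailies.append(grid)
    result.log("daily_ndvi", days=len(dailies), valid_px=n_valid, masked_px=n_masked)
    return dailies


def _composite(dailies: list[IndexGrid], cadence: str, result: PipelineResult,
               scenes: list[ReflectanceScene]) -> dict[CompositePeriod, IndexGrid]:
    groups: dict[CompositePeriod, list[IndexGrid]] = {}
    for scene, grid in zip(scenes_sorted(scenes), dailies):
        period = periods.period_for(scene.date, cadence)
        groups.setdefault(period, []).append(grid)
    out = {}
    for period in sorted(groups):
        out[period] = compositing.mvc(groups[period], period)
    result.log("mvc", periods=len(out), cadence=cadence)
    return out


def scenes_sorted(scenes: list[ReflectanceScene]) -> list[ReflectanceScene]:
    seen: dict[_dt.date, ReflectanceScene] = {}
    for s in scenes:
        seen.setdefault(s.date, s)
    return [seen[d] for d in sorted(seen)]


def save_archive(stack: clim.ClimatologyStack, directory: str | Path) -> None:
    """Persist per-(year, week) composites as float32 rasters plus encoded
    multi-year reference products, named by the layer convention."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for week, per_year in stack.weeks.items():
        for year, grid in per_year.items():
            period = _period(stack.cadence, year, week)
            write_float_grid(
                np.where(grid.nodata_mask, np.nan, grid.values),
                grid.geometry,
                directory / (periods.layer_name(IndexKind.NDVI, period) + _ARCHIVE_SUFFIX),
            )
        for stat in clim.STATS:
            derived = stack.derived(week, stat)
            name = periods.multiyear_layer_name(stack.cadence, week, stat)
            write_product(encoding.encode_grid(derived), directory / (name + ".tif"))


def load_archive(directory: str | Path, cadence: str = WEEKLY) -> clim.ClimatologyStack | None:
    """Rebuild a climatology stack from a persisted archive directory."""
    directory = Path(directory)
    files = sorted(directory.glob(f"*{_ARCHIVE_SUFFIX}")) if directory.is_dir() else []
    if not files:
        return None
    stack = None
    for f in files:
        parsed = periods.parse_layer_name(f.name[: -len(_ARCHIVE_SUFFIX)])
        if parsed.period is None or parsed.cadence != cadence:
            continue
        vals, geom = read_float_grid(f)
        mask = ~np.isfinite(vals)
        grid = IndexGrid(values=vals, nodata_mask=mask, kind=IndexKind.NDVI,
                         geometry=geom, period=parsed.period)
        if stack is None:
            stack = clim.ClimatologyStack(geometry=geom, cadence=cadence)
        stack.insert(grid, parsed.period.year, parsed.period.week)
    return stack


def _period(cadence: str, year: int, week: int) -> CompositePeriod:
    if cadence == WEEKLY:
        return periods.week_period(year, week)
    return periods.biweekly_period(year, week)


def _derive(product: str, current: IndexGrid, stack: clim.ClimatologyStack,
            year: int, week: int, include_current: bool) -> IndexGrid:
    if product == "NDVI":
        return current
    if product == "VCI":
        lo = clim.reference_for(stack, week, "min", current_year=year,
                                include_current=include_current)
        hi = clim.reference_for(stack, week, "max", current_year=year,
                                include_current=include_current)
        return indices.vci(current, lo, hi)
    if product == "MVCI":
        ref = clim.reference_for(stack, week, "mean", current_year=year,
                                 include_current=include_current)
        return indices.mvci(current, ref)
    if product == "RMVCI":
        ref = clim.reference_for(stack, week, "median", current_year=year,
                                 include_current=include_current)
        return indices.rmvci(current, ref)
    if product == "RVCI":
        return indices.rvci(current, clim.previous_year(stack, year, week))
    raise VegidxError(f"unknown product {product!r}")


def run_pipeline(config: dict) -> PipelineResult:
    """Execute the full production chain described by ``config``.

    Required keys: ``input`` (``synth`` parameters or a ``scenes`` list)
    and ``output_dir``.  Optional: ``aoi``, ``cadence`` (weekly/biweekly),
    ``products`` (default all five), ``archive_dir``, ``reference:
    {include_current: bool}``, ``overwrite``, ``seed``.
    """
    result = PipelineResult()
    cadence = config.get("cadence", WEEKLY)
    if cadence not in (WEEKLY, BIWEEKLY):
        raise VegidxError(f"cadence must be weekly or biweekly, got {cadence!r}")
    products = [p.upper() for p in config.get("products", ["NDVI", "VCI", "MVCI", "RMVCI", "RVCI"])]
    include_current = bool(config.get("reference", {}).get("include_current", False))
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    overwrite = bool(config.get("overwrite", False))

    aoi = _load_aoi(config.get("aoi"))
    scenes = _collect_scenes(config, result)
    dailies = _daily_ndvi(scenes, aoi, result)
    composites = _composite(dailies, cadence, result, scenes)

    stack = None
    archive_dir = config.get("archive_dir")
    if archive_dir:
        stack = load_archive(archive_dir, cadence)
    if stack is None:
        stack = clim.ClimatologyStack(geometry=dailies[0].geometry, cadence=cadence)
    for period, grid in composites.items():
        clim.update(stack, grid, period.year, period.week)
        result.composites[(period.year, period.week)] = grid
    result.stack = stack
    result.log("climatology", weeks=len(stack.weeks), years=len(stack.all_years()))

    for period, current in sorted(composites.items()):
        for product in products:
            path = out_dir / (periods.layer_name(IndexKind[product], period) + ".tif")
            if path.exists() and not overwrite:
                result.skipped.append(path)
                continue
            try:
                grid = _derive(product, current, stack, period.year, period.week, include_current)
            except (EmptyReferenceError, PeriodLookupError) as exc:
                result.errors[f"{product}:{period.year}-{period.week:02d}"] = str(exc)
                continue
            write_product(encoding.encode_grid(grid), path)
            result.written.append(path)

    if archive_dir:
        save_archive(stack, archive_dir)
    result.log(
        "products",
        written=len(result.written),
        skipped=len(result.skipped),
        failed=len(result.errors),
    )
    return result


__all__ = ["PipelineResult", "run_pipeline", "save_archive", "load_archive"]
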