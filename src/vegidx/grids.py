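"""Domain containers shared by every pipeline stage.

The pipeline moves data through three representations:

``ReflectanceScene``
    a dated pair of integer RED/NIR surface-reflectance grids in the
    MOD09GQ digital-number convention (valid range -100..16000), with a
    boolean validity mask and grid geometry;
``IndexGrid``
    a floating per-pixel index field (NDVI, VCI, MVCI, RMVCI or RVCI)
    with a no-data mask; and
``EncodedGrid``
    the 8-bit product raster, values 0..250 with 255 as the no-data
    sentinel (bytes 251-254 are never produced and are rejected on read).

Grids are row-major ``numpy`` arrays; row 0 is the northernmost row and
``origin_x``/``origin_y`` name the top-left *corner* of the raster in map
units.  The tooling is resolution- and CRS-agnostic: the 250 m MODIS
grid is just one geometry it can carry.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import StructuralError

# MOD09GQ surface-reflectance validity bounds (digital numbers).
REFLECTANCE_MIN = -100
REFLECTANCE_MAX = 16000

#: Product no-data sentinel byte.
NODATA_BYTE = 255


class IndexKind(enum.Enum):
    """The five vegetation-index products."""

    NDVI = "NDVI"
    VCI = "VCI"
    MVCI = "MVCI"
    RMVCI = "RMVCI"
    RVCI = "RVCI"

    @property
    def is_ratio(self) -> bool:
        """True for the deviation-ratio indices sharing the piecewise encoding."""
        return self in (IndexKind.MVCI, IndexKind.RMVCI, IndexKind.RVCI)


@dataclass(frozen=True)
class GridGeometry:
    """Raster lattice: shape, top-left corner, square pixel size, CRS id."""

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0
    crs_id: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise StructuralError(f"grid shape must be positive, got {self.n_rows}x{self.n_cols}")
        if self.pixel_size <= 0:
            raise StructuralError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every pixel center, each shaped like the grid."""
        cols = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        rows = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(cols, rows)

    def congruent(self, other: "GridGeometry") -> bool:
        """Same lattice: shape, origin (to a pixel tolerance), size and CRS."""
        tol = 1e-6 * self.pixel_size
        return (
            self.shape == other.shape
            and abs(self.pixel_size - other.pixel_size) <= tol
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and self.crs_id == other.crs_id
        )


def _require_congruent(a: GridGeometry, b: GridGeometry, what: str) -> None:
    if not a.congruent(b):
        raise StructuralError(f"{what}: geometries differ ({a} vs {b})")


@dataclass
class ReflectanceScene:
    """Dated RED/NIR digital-number pair with a validity mask.

    ``valid`` is True where the pixel holds a usable observation.  Band
    values outside the MOD09GQ range [-100, 16000] are *not* rejected at
    construction; :func:`vegidx.encoding.validate_reflectance` masks them.
    """

    red: np.ndarray
    nir: np.ndarray
    valid: np.ndarray
    date: _dt.date
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if not (self.red.shape == self.nir.shape == self.valid.shape):
            raise StructuralError(
                f"band/mask shapes differ: red {self.red.shape}, "
                f"nir {self.nir.shape}, valid {self.valid.shape}"
            )
        if self.red.shape != self.geometry.shape:
            raise StructuralError(
                f"band shape {self.red.shape} != geometry shape {self.geometry.shape}"
            )
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class IndexGrid:
    """Floating per-pixel index field with a no-data mask.

    ``nodata_mask`` is True where the pixel has no defined value; masked
    cells carry NaN in ``values``.  ``period`` is whatever
    :class:`vegidx.periods.CompositePeriod` the grid summarizes (None for
    bare reference fields).
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    kind: IndexKind
    geometry: GridGeometry
    period: object = None
    #: number of daily grids that contributed (set by the compositor).
    n_days: int | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.nodata_mask.shape:
            raise StructuralError("values/nodata_mask shapes differ")
        if self.values.shape != self.geometry.shape:
            raise StructuralError("values shape != geometry shape")
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.values[self.nodata_mask] = np.nan

    def with_values(self, values: np.ndarray, mask: np.ndarray, kind: IndexKind) -> "IndexGrid":
        return replace(self, values=values, nodata_mask=mask, kind=kind)


@dataclass
class EncodedGrid:
    """8-bit product raster: values 0..250, no-data 255; 251-254 never occur."""

    bytes: np.ndarray
    kind: IndexKind
    geometry: GridGeometry
    period: object = None

    def __post_init__(self) -> None:
        self.bytes = np.asarray(self.bytes, dtype=np.uint8)
        if self.bytes.shape != self.geometry.shape:
            raise StructuralError("bytes shape != geometry shape")


__all__ = [
    "IndexKind",
    "GridGeometry",
    "ReflectanceScene",
    "IndexGrid",
    "EncodedGrid",
    "REFLECTANCE_MIN",
    "REFLECTANCE_MAX",
    "NODATA_BYTE",
]
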