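"""Core raster containers and TIFF-backed I/O.

A :class:`RasterGrid` is a single-band raster: a 2-D value array plus the
minimal geometry needed by the rest of the package (ground pixel size, origin
of the top-left pixel's outer corner, per-cell nodata mask) and optional
time tags (16-day composite period index and calendar year).  Arrays are
row-major with the row index increasing southward, the dominant convention
for north-up imagery.

Grids are stored on disk as single-band float TIFFs with the geometry
serialized as JSON in the ImageDescription tag and nodata cells replaced by a
sentinel value recorded there.  In memory nodata is always a boolean mask so
the sentinel never leaks into arithmetic.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "QualityState",
    "QualityMask",
    "CompositePeriod",
    "PERIODS_PER_YEAR",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
    "composite_period_of",
    "max_composite",
]

#: Fixed number of 16-day composite windows per calendar year, anchored at
#: January 1; the last window is truncated at December 31.
PERIODS_PER_YEAR = 23

_NODATA_SENTINEL = -9999.0


class GeometryError(ValueError):
    """Raised when rasters that must share geometry do not."""


class QualityState(IntEnum):
    """Per-pixel quality category driving inclusion/exclusion."""

    CLEAR = 0
    CLOUD = 1
    CIRRUS = 2
    SHADOW = 3
    MISSING = 4


@dataclass
class RasterGrid:
    """Single-band raster with geometry, nodata mask and time tags."""

    values: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: np.ndarray | None = None
    period: int | None = None
    year: int | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.nodata is None:
            self.nodata = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise ValueError("nodata mask shape must match values shape")
        if not np.all(np.isfinite(self.values[~self.nodata])):
            raise ValueError("non-nodata values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """Flat array of the non-nodata cell values."""
        return self.values[~self.nodata]

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy(), nodata=self.nodata.copy())

    def same_geometry(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_size, other.pixel_size
        )

    def require_same_geometry(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}@{self.pixel_size} vs "
                f"{other.shape}@{other.pixel_size}"
            )


@dataclass
class QualityMask:
    """Categorical per-pixel quality states aligned with a :class:`RasterGrid`."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2 or self.states.size == 0:
            raise ValueError("states must be a non-empty 2-D array")
        if self.states.max(initial=0) > max(QualityState):
            raise ValueError("states contain codes outside the quality alphabet")

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    def is_clear(self) -> np.ndarray:
        return self.states == QualityState.CLEAR

    def fraction(self, state: QualityState) -> float:
        return float(np.mean(self.states == state))

    @classmethod
    def all_clear(cls, shape: tuple[int, int]) -> "QualityMask":
        return cls(np.zeros(shape, dtype=np.uint8))


@dataclass(frozen=True)
class CompositePeriod:
    """One of the 23 fixed 16-day windows per year, anchored at January 1."""

    year: int
    index: int

    def __post_init__(self) -> None:
        if not 1 <= self.index <= PERIODS_PER_YEAR:
            raise ValueError(f"period index must be in [1, {PERIODS_PER_YEAR}]")

    @property
    def start_day_of_year(self) -> int:
        return 1 + 16 * (self.index - 1)


def composite_period_of(date: _dt.date) -> CompositePeriod:
    """Map a calendar date to its 16-day composite period.

    Window ``i`` covers days-of-year ``16*(i-1)+1 .. 16*i``; the 23rd window
    absorbs the trailing 13-14 days of the year.
    """
    doy = date.timetuple().tm_yday
    index = min((doy - 1) // 16 + 1, PERIODS_PER_YEAR)
    return CompositePeriod(year=date.year, index=index)


def max_composite(stack: Sequence[RasterGrid]) -> RasterGrid:
    """Per-pixel maximum over a stack of co-registered grids.

    A pixel is nodata only where it is nodata in every layer.  This is the
    maximum-value compositing used to collapse sub-period acquisitions into
    one 16-day scene.
    """
    if len(stack) == 0:
        raise ValueError("max_composite requires a non-empty stack")
    first = stack[0]
    for g in stack[1:]:
        first.require_same_geometry(g)
    vals = np.stack([np.where(g.nodata, -np.inf, g.values) for g in stack])
    out = vals.max(axis=0)
    all_nodata = ~np.isfinite(out)
    out[all_nodata] = 0.0
    return RasterGrid(
        values=out,
        pixel_size=first.pixel_size,
        origin=first.origin,
        nodata=all_nodata,
        period=first.period,
        year=first.year,
        crs=first.crs,
    )


# ---------------------------------------------------------------------------
# TIFF I/O


def write_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as a single-band float TIFF with JSON geometry metadata."""
    arr = grid.values.astype(np.float64, copy=True)
    arr[grid.nodata] = _NODATA_SENTINEL
    meta = {
        "kind": "grid",
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
        "nodata_value": _NODATA_SENTINEL,
        "period": grid.period,
        "year": grid.year,
        "crs": grid.crs,
    }
    tifffile.imwrite(path, arr, description=json.dumps(meta, sort_keys=True))


def read_grid(path: str | Path, band: int = 1) -> RasterGrid:
    """Read a grid written by :func:`write_grid` (or any float TIFF).

    ``band`` is 1-based and selects a plane of a multi-band file; files
    written by this package are always single-band.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 3:
        # band-major (bands, rows, cols) or interleaved (rows, cols, bands)
        n_bands = arr.shape[0] if arr.shape[0] < arr.shape[-1] else arr.shape[-1]
        if not 1 <= band <= n_bands:
            raise ValueError(f"band {band} not in file with {n_bands} bands")
        arr = arr[band - 1] if arr.shape[0] == n_bands else arr[..., band - 1]
    elif band != 1:
        raise ValueError(f"band {band} requested from a single-band file")
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    arr = np.asarray(arr, dtype=float)
    nodata_value = meta.get("nodata_value", _NODATA_SENTINEL)
    nodata = np.zeros(arr.shape, dtype=bool) if nodata_value is None else (
        arr == nodata_value
    )
    nodata |= ~np.isfinite(arr)
    arr = arr.copy()
    arr[nodata] = 0.0
    origin = tuple(meta.get("origin", (0.0, 0.0)))
    return RasterGrid(
        values=arr,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=(float(origin[0]), float(origin[1])),
        nodata=nodata,
        period=meta.get("period"),
        year=meta.get("year"),
        crs=meta.get("crs"),
    )


def write_mask(mask: QualityMask, path: str | Path) -> None:
    """Serialize a quality mask as a uint8 TIFF (codes 0..4)."""
    meta = {"kind": "quality_mask", "codes": {s.name: int(s) for s in QualityState}}
    tifffile.imwrite(path, mask.states, description=json.dumps(meta, sort_keys=True))


def read_mask(path: str | Path) -> QualityMask:
    return QualityMask(np.asarray(tifffile.imread(path), dtype=np.uint8))
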