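"""NDVI computation, quality masking, valid-value filtering and resampling.

NDVI = (NIR - RED) / (NIR + RED) on surface reflectance, the standard
normalized difference vegetation index.  Pixels flagged cloud, cirrus, cloud
shadow or missing are removed before any model sees them, and — following the
convention that negative NDVI indicates water, snow, cloud or bare rock
rather than vegetation — only NDVI >= 0 survives the valid-value filter.

Resolution changes between the coarse (~250 m class) and fine (~30 m class)
grids are restricted to an integer factor so that coarse/fine pixel
correspondence is exact: fine-to-coarse is the mean over factor x factor
blocks of valid pixels, coarse-to-fine is nearest-neighbour block replication
(value preserving; no fabricated intermediate NDVI values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import GeometryError, QualityMask, QualityState, RasterGrid

__all__ = [
    "ReflectancePair",
    "compute_ndvi",
    "apply_quality_mask",
    "filter_valid",
    "aggregate_to_coarse",
    "resample_to_fine",
]


@dataclass
class ReflectancePair:
    """Co-registered red and near-infrared surface-reflectance grids."""

    red: RasterGrid
    nir: RasterGrid

    def __post_init__(self) -> None:
        self.red.require_same_geometry(self.nir)
        for name, g in (("red", self.red), ("nir", self.nir)):
            if np.any(g.values[~g.nodata] < 0):
                raise ValueError(f"{name} reflectance contains negative values")


def compute_ndvi(bands: ReflectancePair) -> RasterGrid:
    """(NIR - RED) / (NIR + RED); nodata where either band is or the sum is 0."""
    red, nir = bands.red, bands.nir
    denom = nir.values + red.values
    nodata = red.nodata | nir.nodata | (denom == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nodata, 0.0, (nir.values - red.values) / np.where(denom == 0, 1.0, denom))
    return RasterGrid(
        values=ndvi,
        pixel_size=red.pixel_size,
        origin=red.origin,
        nodata=nodata,
        period=red.period,
        year=red.year,
        crs=red.crs,
    )


def apply_quality_mask(ndvi: RasterGrid, mask: QualityMask) -> RasterGrid:
    """Set pixels flagged cloud/cirrus/shadow/missing to nodata."""
    if mask.shape != ndvi.shape:
        raise GeometryError(f"mask shape {mask.shape} != grid shape {ndvi.shape}")
    out = ndvi.copy()
    out.nodata = ndvi.nodata | (mask.states != QualityState.CLEAR)
    return out


def filter_valid(ndvi: RasterGrid) -> RasterGrid:
    """Keep only NDVI >= 0; negative values (water/snow/cloud) become nodata."""
    out = ndvi.copy()
    out.nodata = ndvi.nodata | (ndvi.values < 0)
    return out


def _crop_to_factor(grid: RasterGrid, factor: int) -> RasterGrid:
    rows, cols = grid.shape
    r, c = rows - rows % factor, cols - cols % factor
    if (r, c) != (rows, cols):
        warnings.warn(
            f"grid {rows}x{cols} not divisible by factor {factor}; "
            f"cropping trailing rows/columns to {r}x{c}",
            stacklevel=3,
        )
        out = grid.copy()
        out.values = out.values[:r, :c]
        out.nodata = out.nodata[:r, :c]
        return out
    return grid


def aggregate_to_coarse(
    fine: RasterGrid, factor: int, min_valid_fraction: float = 0.5
) -> RasterGrid:
    """Block-mean a fine grid down by an integer factor.

    Each coarse pixel is the mean of the valid pixels of its factor x factor
    block; blocks whose valid fraction falls below ``min_valid_fraction``
    become nodata so a handful of surviving pixels cannot stand in for a
    whole coarse cell.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return fine.copy()
    fine = _crop_to_factor(fine, factor)
    rows, cols = fine.shape
    vals = np.where(fine.nodata, 0.0, fine.values)
    vals = vals.reshape(rows // factor, factor, cols // factor, factor)
    valid = (~fine.nodata).reshape(rows // factor, factor, cols // factor, factor)
    count = valid.sum(axis=(1, 3))
    total = vals.sum(axis=(1, 3))
    nodata = count < max(min_valid_fraction * factor * factor, 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(nodata, 0.0, total / np.maximum(count, 1))
    return RasterGrid(
        values=mean,
        pixel_size=fine.pixel_size * factor,
        origin=fine.origin,
        nodata=nodata,
        period=fine.period,
        year=fine.year,
        crs=fine.crs,
    )


def resample_to_fine(
    coarse: RasterGrid, factor: int, method: str = "nearest"
) -> RasterGrid:
    """Upsample a coarse grid by an integer factor.

    ``nearest`` (default) replicates each coarse pixel into a factor x factor
    block, so no NDVI value is fabricated; ``bilinear`` interpolates and is
    offered for smoother visual output.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return coarse.copy()
    if method == "nearest":
        vals = np.repeat(np.repeat(coarse.values, factor, axis=0), factor, axis=1)
        nodata = np.repeat(np.repeat(coarse.nodata, factor, axis=0), factor, axis=1)
    elif method == "bilinear":
        filled = np.where(coarse.nodata, np.nan, coarse.values)
        vals = ndimage.zoom(np.nan_to_num(filled, nan=0.0), factor, order=1)
        nodata = (
            ndimage.zoom(coarse.nodata.astype(float), factor, order=0) > 0.5
        )
        vals = np.where(nodata, 0.0, vals)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return RasterGrid(
        values=vals,
        pixel_size=coarse.pixel_size / factor,
        origin=coarse.origin,
        nodata=nodata,
        period=coarse.period,
        year=coarse.year,
        crs=coarse.crs,
    )
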