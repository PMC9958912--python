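"""Gap filling: replace cloud/shadow/missing fine pixels with model
predictions driven by the coarse grid.

Clear, valid fine pixels are preserved bit-exactly — the observed data is
never touched.  Pixels polluted by cloud, cirrus or cloud shadow, or missing
from fine coverage, are predicted by the trained network from the co-located
coarse NDVI; where the coarse sensor is also invalid the pixel stays nodata
(there is no basis in the method for spatial interpolation of double gaps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ga_ann import GAANNModel, forward
from .raster import QualityMask, RasterGrid

__all__ = ["ReconstructionOutput", "reconstruct", "reconstruct_series"]


@dataclass
class ReconstructionOutput:
    """A filled grid plus bookkeeping: where predictions were written and
    counts of preserved / filled / still-missing pixels."""

    filled: RasterGrid
    fill_mask: np.ndarray
    provenance: dict

    @property
    def n_filled(self) -> int:
        return int(self.fill_mask.sum())


def reconstruct(
    fine: RasterGrid,
    fine_mask: QualityMask,
    coarse_on_common_grid: RasterGrid,
    model: GAANNModel,
) -> ReconstructionOutput:
    """Fill non-clear pixels of ``fine`` from ``coarse_on_common_grid``.

    The three grids share geometry (the coarse input having been replicated
    to the common fine grid).  Output partition: preserved clear pixels,
    filled pixels (``fill_mask``), and pixels invalid in both sensors, which
    remain nodata.
    """
    fine.require_same_geometry(coarse_on_common_grid)
    if fine_mask.shape != fine.shape:
        raise ValueError(f"mask shape {fine_mask.shape} != grid shape {fine.shape}")
    to_fill = ~fine_mask.is_clear() | fine.nodata
    fill_mask = to_fill & ~coarse_on_common_grid.nodata
    values = fine.values.copy()
    nodata = to_fill & ~fill_mask
    if fill_mask.any():
        values[fill_mask] = forward(model, coarse_on_common_grid.values[fill_mask])
    values[nodata] = 0.0
    filled = RasterGrid(
        values=values,
        pixel_size=fine.pixel_size,
        origin=fine.origin,
        nodata=nodata,
        period=fine.period,
        year=fine.year,
        crs=fine.crs,
    )
    return ReconstructionOutput(
        filled=filled,
        fill_mask=fill_mask,
        provenance={
            "period": fine.period,
            "n_preserved": int((~to_fill).sum()),
            "n_filled": int(fill_mask.sum()),
            "n_unfillable": int(nodata.sum()),
        },
    )


def reconstruct_series(
    fine_series: list[tuple[RasterGrid, QualityMask]],
    coarse_series: list[RasterGrid],
    model: GAANNModel,
) -> list[ReconstructionOutput]:
    """Per-period reconstruction of an aligned time series."""
    if len(fine_series) != len(coarse_series):
        raise ValueError("fine and coarse series lengths differ")
    out = []
    for (fine, mask), coarse in zip(fine_series, coarse_series):
        if fine.period != coarse.period:
            raise ValueError(
                f"period misalignment: fine {fine.period} vs coarse {coarse.period}"
            )
        out.append(reconstruct(fine, mask, coarse, model))
    return out
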