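"""Clear-sky coarse/fine pixel pairs: extraction, sampling, train/test split.

The training unit of the method is the pixel pair: the coarse-sensor NDVI and
fine-sensor NDVI at the same position and composite period, both unpolluted
by clouds.  Pairs are extracted on a common grid (one of the two inputs
having been resampled by :mod:`ndvigap.preprocess`), uniformly subsampled to
the desired number of random points, and split 80/20 for self-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "PixelPairSet",
    "extract_pairs",
    "sample_random_points",
    "split_train_validation",
    "concat_pairs",
    "pairs_from_arrays",
    "save_pairs",
    "load_pairs",
]


@dataclass
class PixelPairSet:
    """Ordered collection of co-located (coarse NDVI, fine NDVI) samples.

    Stored columnar for vectorized training; ``periods`` is -1 where the
    composite period is unset.  ``provenance`` records how the set was made
    (source grids, sampling seed or "exhaustive", ...).
    """

    rows: np.ndarray
    cols: np.ndarray
    coarse: np.ndarray
    fine: np.ndarray
    periods: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.coarse = np.asarray(self.coarse, dtype=float)
        self.fine = np.asarray(self.fine, dtype=float)
        self.periods = np.asarray(self.periods, dtype=np.int64)
        n = len(self.rows)
        for name in ("cols", "coarse", "fine", "periods"):
            if len(getattr(self, name)) != n:
                raise ValueError("pair columns must have equal length")
        if n:
            key = np.stack([self.rows, self.cols, self.periods])
            if np.unique(key, axis=1).shape[1] != n:
                raise ValueError("duplicate (row, col, period) entries")

    def __len__(self) -> int:
        return len(self.rows)

    def take(self, idx: np.ndarray, provenance: dict | None = None) -> "PixelPairSet":
        return PixelPairSet(
            rows=self.rows[idx],
            cols=self.cols[idx],
            coarse=self.coarse[idx],
            fine=self.fine[idx],
            periods=self.periods[idx],
            provenance=dict(provenance or self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.rows,
                "col": self.cols,
                "period": self.periods,
                "coarse_ndvi": self.coarse,
                "fine_ndvi": self.fine,
            }
        )


def extract_pairs(
    coarse_on_common_grid: RasterGrid, fine_on_common_grid: RasterGrid
) -> PixelPairSet:
    """One pair per pixel where both grids are valid, in row-major order."""
    coarse_on_common_grid.require_same_geometry(fine_on_common_grid)
    valid = ~coarse_on_common_grid.nodata & ~fine_on_common_grid.nodata
    rows, cols = np.nonzero(valid)
    period = fine_on_common_grid.period
    if period is None:
        period = coarse_on_common_grid.period
    return PixelPairSet(
        rows=rows,
        cols=cols,
        coarse=coarse_on_common_grid.values[rows, cols],
        fine=fine_on_common_grid.values[rows, cols],
        periods=np.full(len(rows), -1 if period is None else period),
        provenance={"sampling": "exhaustive", "period": period},
    )


def sample_random_points(pairs: PixelPairSet, n: int, seed: int) -> PixelPairSet:
    """Uniform sample of ``n`` pairs without replacement, deterministic per seed."""
    if n > len(pairs):
        raise ValueError(f"requested {n} points but only {len(pairs)} pairs available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    prov = dict(pairs.provenance)
    prov.update({"sampling": "uniform", "n": n, "seed": seed})
    return pairs.take(idx, provenance=prov)


def split_train_validation(
    pairs: PixelPairSet, train_fraction: float = 0.8, seed: int = 0
) -> tuple[PixelPairSet, PixelPairSet]:
    """Disjoint random partition; train size = round(train_fraction * n)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    n_train = int(round(train_fraction * len(pairs)))
    n_train = min(max(n_train, 1), len(pairs) - 1)
    prov = dict(pairs.provenance)
    prov.update({"split_seed": seed, "train_fraction": train_fraction})
    return (
        pairs.take(np.sort(perm[:n_train]), provenance={**prov, "split": "train"}),
        pairs.take(np.sort(perm[n_train:]), provenance={**prov, "split": "validation"}),
    )


def concat_pairs(parts: list[PixelPairSet]) -> PixelPairSet:
    """Pool pair sets (e.g. across composite periods) into one training set."""
    if not parts:
        raise ValueError("nothing to concatenate")
    return PixelPairSet(
        rows=np.concatenate([p.rows for p in parts]),
        cols=np.concatenate([p.cols for p in parts]),
        coarse=np.concatenate([p.coarse for p in parts]),
        fine=np.concatenate([p.fine for p in parts]),
        periods=np.concatenate([p.periods for p in parts]),
        provenance={"sampling": "pooled", "n_parts": len(parts)},
    )


def pairs_from_arrays(
    coarse: np.ndarray, fine: np.ndarray, provenance: dict | None = None
) -> PixelPairSet:
    """Wrap parallel value arrays as a pair set (synthetic-pair convenience)."""
    coarse = np.asarray(coarse, dtype=float).ravel()
    fine = np.asarray(fine, dtype=float).ravel()
    if coarse.shape != fine.shape:
        raise ValueError("coarse and fine arrays must have equal length")
    n = len(coarse)
    return PixelPairSet(
        rows=np.arange(n),
        cols=np.zeros(n, dtype=np.int64),
        coarse=coarse,
        fine=fine,
        periods=np.full(n, -1),
        provenance=dict(provenance or {"sampling": "arrays"}),
    )


def save_pairs(pairs: PixelPairSet, path: str | Path) -> None:
    pairs.to_frame().to_csv(path, index=False)


def load_pairs(path: str | Path) -> PixelPairSet:
    df = pd.read_csv(path)
    return PixelPairSet(
        rows=df["row"].to_numpy(),
        cols=df["col"].to_numpy(),
        coarse=df["coarse_ndvi"].to_numpy(),
        fine=df["fine_ndvi"].to_numpy(),
        periods=df["period"].to_numpy(),
        provenance={"source": str(path)},
    )
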