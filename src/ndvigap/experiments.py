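"""Sensitivity harnesses: hidden-layer sweep, random-point-count sweep,
resampling-direction comparison, and the 80/20 self-validation protocol.

Each harness runs the full training protocol at several parameter levels
with everything else held fixed, replicated over a list of seeds (a single
genetic-algorithm run with a population of 10 is noisy, so levels are
compared on seed-averaged metrics with dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ga_ann import GAConfig, NetworkSpec, train
from .pairing import PixelPairSet, extract_pairs, sample_random_points
from .preprocess import aggregate_to_coarse, resample_to_fine
from .synthetic import SyntheticScene

__all__ = [
    "SweepResult",
    "hidden_layer_sweep",
    "point_count_sweep",
    "resampling_direction_experiment",
    "self_validation",
]


@dataclass
class SweepResult:
    """Per-(level, seed) validation metrics plus seed-aggregated rows."""

    axis: str
    levels: list
    table: pd.DataFrame  # columns: level, seed, rmse, mae, r
    provenance: dict

    @property
    def aggregated(self) -> pd.DataFrame:
        return (
            self.table.groupby("level")[["rmse", "mae", "r"]]
            .agg(["mean", "std"])
            .reset_index()
        )

    def level_mean(self, level, metric: str = "rmse") -> float:
        sub = self.table[self.table["level"] == level]
        return float(sub[metric].mean())


def _run_rows(
    axis: str,
    pair_sets: dict,
    spec_for,
    config: GAConfig | None,
    seeds: Sequence[int],
) -> pd.DataFrame:
    rows = []
    for level, pairs_by_seed in pair_sets.items():
        for seed in seeds:
            pairs = pairs_by_seed(seed) if callable(pairs_by_seed) else pairs_by_seed
            res = train(pairs, spec=spec_for(level), config=config, seed=seed)
            rows.append(
                {
                    "level": level,
                    "seed": seed,
                    "rmse": res.validation_metrics["rmse"],
                    "mae": res.validation_metrics["mae"],
                    "r": res.validation_metrics.get("r", np.nan),
                }
            )
    return pd.DataFrame(rows)


def hidden_layer_sweep(
    pairs: PixelPairSet,
    levels: Sequence[int] = range(3, 10),
    seeds: Sequence[int] = range(5),
    config: GAConfig | None = None,
) -> SweepResult:
    """Train at several hidden-layer sizes on identical data and splits."""
    levels = list(levels)
    table = _run_rows(
        "hidden_layers",
        {h: pairs for h in levels},
        lambda h: NetworkSpec(n_hidden=h),
        config,
        seeds,
    )
    return SweepResult(
        axis="hidden_layers",
        levels=levels,
        table=table,
        provenance={"n_pairs": len(pairs), "seeds": list(seeds)},
    )


def point_count_sweep(
    pairs: PixelPairSet,
    levels: Sequence[int] = (500, 1000, 2000),
    seeds: Sequence[int] = range(5),
    config: GAConfig | None = None,
) -> SweepResult:
    """Train on different numbers of uniformly sampled random points.

    The sample at each level is drawn per seed (same seed, same sample
    across levels would nest only by chance; instead each (level, seed) draws
    its own uniform subset), everything else identical.
    """
    levels = list(levels)
    if max(levels) > len(pairs):
        raise ValueError(
            f"largest level {max(levels)} exceeds available pairs {len(pairs)}"
        )
    pair_sets = {
        n: (lambda seed, n=n: sample_random_points(pairs, n, seed)) for n in levels
    }
    table = _run_rows(
        "random_points", pair_sets, lambda n: NetworkSpec(), config, seeds
    )
    return SweepResult(
        axis="random_points",
        levels=levels,
        table=table,
        provenance={"n_pairs": len(pairs), "seeds": list(seeds)},
    )


def resampling_direction_experiment(
    scene: SyntheticScene,
    seeds: Sequence[int] = range(10),
    n_points: int = 500,
    config: GAConfig | None = None,
) -> SweepResult:
    """Compare the two pairing directions on one scene.

    Arm ``aggregate-down`` builds pairs at the coarse grid (observed fine
    aggregated by block mean), arm ``replicate-up`` at the fine grid (coarse
    replicated by nearest neighbour).  Both arms use the same scene, seeds
    and number of sampled points, so any difference comes from the pairing
    direction alone.  Aggregating averages away fine-scale noise and
    sub-block heterogeneity, which is why the aggregate-down arm tends to
    validate better when fine-scale noise is present.
    """
    factor = scene.truth_fine.shape[0] // scene.coarse.shape[0]
    fine_down = aggregate_to_coarse(scene.observed_fine, factor)
    pairs_down = extract_pairs(scene.coarse, fine_down)
    coarse_up = resample_to_fine(scene.coarse, factor)
    pairs_up = extract_pairs(coarse_up, scene.observed_fine)
    n = min(n_points, len(pairs_down), len(pairs_up))
    pair_sets = {
        "aggregate-down": (lambda seed: sample_random_points(pairs_down, n, seed)),
        "replicate-up": (lambda seed: sample_random_points(pairs_up, n, seed)),
    }
    table = _run_rows(
        "resampling_direction", pair_sets, lambda _: NetworkSpec(), config, seeds
    )
    return SweepResult(
        axis="resampling_direction",
        levels=["aggregate-down", "replicate-up"],
        table=table,
        provenance={
            "n_points": n,
            "seeds": list(seeds),
            "factor": factor,
            "period": scene.period.index,
        },
    )


def self_validation(
    pairs: PixelPairSet,
    config: GAConfig | None = None,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> dict:
    """80/20 self-validation: train on 80% of the pairs, report RMSE, MAE
    and Pearson r on the held-out 20%."""
    res = train(pairs, config=config, seed=seed, train_fraction=train_fraction)
    out = dict(res.validation_metrics)
    out["train_fraction"] = train_fraction
    out["seed"] = seed
    return out
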