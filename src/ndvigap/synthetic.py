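"""Deterministic synthetic coarse/fine scene pairs with known ground truth.

The generator emulates the structure of a fine-sensor (~30 m class) NDVI
scene and its coarse-sensor (~250 m class) 16-day composite counterpart:

* a fine "truth" field built from a fixed set of land-cover patches (a
  smoothed random partition), each following a seasonal sinusoid that rises
  to a mid-year peak scaled by a per-class amplitude, plus low-amplitude
  spatial texture — the rise-then-fall trajectory typical of cropland and
  forest NDVI;
* a coarse counterpart equal to a known monotone sensor distortion ``g``
  applied to the block mean of the truth (default power law g(v) = v^0.85,
  standing in for the unknown nonlinear inter-sensor relationship), plus
  independent additive Gaussian noise;
* an observed fine grid equal to truth plus noise, with blob-shaped cloud
  masks (elliptical blobs with an offset shadow rim) hiding a configurable
  fraction of the scene.

Everything is a pure function of (config, period): child random streams are
derived by hashing (master seed, period, component name), so adding a
component never shifts an existing stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pairing import PixelPairSet, extract_pairs, sample_random_points
from .preprocess import aggregate_to_coarse, apply_quality_mask, resample_to_fine
from .raster import CompositePeriod, QualityMask, QualityState, RasterGrid

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_truth",
    "generate_cloud_mask",
    "generate_scene",
    "generate_year",
    "scene_pairs",
]

# Per-class winter baseline NDVI and seasonal amplitude share, loosely
# urban / grassland / cropland / forest.
_CLASS_BASE = np.array([0.10, 0.14, 0.18, 0.22])
_CLASS_AMP = np.array([0.25, 0.50, 0.75, 1.00])


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic year of scenes."""

    fine_shape: tuple[int, int] = (256, 256)
    factor: int = 8
    n_periods: int = 23
    seasonal_amplitude: float = 0.4
    distortion: str = "power"
    distortion_gamma: float = 0.85
    noise_sigma: float = 0.02
    cloud_fraction: float = 0.3
    blob_scale: int = 12
    fine_pixel_size: float = 30.0
    year: int = 2020
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.fine_shape
        if r % self.factor or c % self.factor:
            raise ValueError("fine_shape must be divisible by factor")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.distortion not in ("power", "logistic", "identity"):
            raise ValueError(f"unknown distortion {self.distortion!r}")

    def distort(self, v: np.ndarray) -> np.ndarray:
        """The monotone sensor distortion g, invertible on [0, 1]."""
        v = np.asarray(v, dtype=float)
        if self.distortion == "identity":
            return v.copy()
        if self.distortion == "power":
            return np.power(np.clip(v, 0.0, None), self.distortion_gamma)
        # logistic, min-max normalized so g(0) = 0, g(1) = 1
        k, v0 = 6.0, 0.45
        raw = 1.0 / (1.0 + np.exp(-k * (v - v0)))
        lo = 1.0 / (1.0 + np.exp(k * v0))
        hi = 1.0 / (1.0 + np.exp(-k * (1.0 - v0)))
        return (raw - lo) / (hi - lo)


@dataclass
class SyntheticScene:
    """One period's worth of mutually consistent grids."""

    truth_fine: RasterGrid
    observed_fine: RasterGrid
    fine_mask: QualityMask
    coarse: RasterGrid
    period: CompositePeriod
    config: SceneConfig = field(repr=False, default=None)


def _child_rng(seed: int, period: int, component: str) -> np.random.Generator:
    token = f"{seed}:{period}:{component}".encode()
    return np.random.default_rng(zlib.crc32(token))


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field smoothed at the given scale."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def _static_layers(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Period-independent scene structure: winter base, amplitude map, texture."""
    shape = config.fine_shape
    patch_rng = _child_rng(config.seed, 0, "patches")
    patch_field = _smooth_field(patch_rng, shape, sigma=max(shape) / 12)
    # quantile thresholds -> 4 roughly equal land-cover classes
    edges = np.quantile(patch_field, [0.25, 0.5, 0.75])
    classes = np.digitize(patch_field, edges)
    base = _CLASS_BASE[classes]
    amp = _CLASS_AMP[classes] * config.seasonal_amplitude
    # soften class boundaries so sub-block heterogeneity stays moderate
    base = ndimage.gaussian_filter(base, 5.0, mode="wrap")
    amp = ndimage.gaussian_filter(amp, 5.0, mode="wrap")
    tex_rng = _child_rng(config.seed, 0, "texture")
    texture = 0.012 * _smooth_field(tex_rng, shape, sigma=3.0)
    return base, amp, texture


def seasonal_weight(period: int, n_periods: int) -> float:
    """Unimodal seasonal multiplier: 0 at the year's edges, 1 mid-year."""
    return float(np.sin(np.pi * (period - 0.5) / n_periods))


def generate_truth(config: SceneConfig, period: int) -> RasterGrid:
    """The fine-resolution ground-truth NDVI field for one period."""
    base, amp, texture = _static_layers(config)
    s = seasonal_weight(period, config.n_periods)
    values = np.clip(base + s * amp + texture, 0.0, 1.0)
    return RasterGrid(
        values=values,
        pixel_size=config.fine_pixel_size,
        period=period,
        year=config.year,
    )


def generate_cloud_mask(config: SceneConfig, period: int) -> QualityMask:
    """Blob-shaped cloud cover with an offset shadow rim.

    Random elliptical blobs are unioned until the masked (cloud + shadow)
    fraction reaches ``cloud_fraction``; the shadow rim is the cloud
    footprint displaced by a fixed offset, minus the cloud itself.
    """
    shape = config.fine_shape
    states = np.zeros(shape, dtype=np.uint8)
    if config.cloud_fraction == 0:
        return QualityMask(states)
    rng = _child_rng(config.seed, period, "clouds")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cloud = np.zeros(shape, dtype=bool)
    shift = max(2, config.blob_scale // 4)
    total = np.prod(shape)
    for _ in range(10_000):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ay = config.blob_scale * rng.uniform(0.5, 1.5)
        ax = config.blob_scale * rng.uniform(0.5, 1.5)
        theta = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        cloud |= (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
        shadow = np.roll(cloud, (shift, shift), axis=(0, 1)) & ~cloud
        if (cloud.sum() + shadow.sum()) / total >= config.cloud_fraction:
            break
    states[shadow] = QualityState.SHADOW
    states[cloud] = QualityState.CLOUD
    return QualityMask(states)


def generate_scene(config: SceneConfig, period: int) -> SyntheticScene:
    """Truth, noisy masked observation, and distorted coarse counterpart."""
    truth = generate_truth(config, period)
    mask = generate_cloud_mask(config, period)

    fine_noise = _child_rng(config.seed, period, "fine_noise")
    observed_vals = truth.values
    if config.noise_sigma > 0:
        observed_vals = np.clip(
            truth.values + fine_noise.normal(0, config.noise_sigma, truth.shape),
            0.0,
            1.0,
        )
    observed = RasterGrid(
        values=observed_vals.copy(),
        pixel_size=truth.pixel_size,
        period=period,
        year=config.year,
    )
    observed = apply_quality_mask(observed, mask)

    block_mean = aggregate_to_coarse(truth, config.factor, min_valid_fraction=0.0)
    coarse_vals = config.distort(block_mean.values)
    if config.noise_sigma > 0:
        coarse_noise = _child_rng(config.seed, period, "coarse_noise")
        coarse_vals = np.clip(
            coarse_vals + coarse_noise.normal(0, config.noise_sigma, coarse_vals.shape),
            0.0,
            1.0,
        )
    coarse = RasterGrid(
        values=coarse_vals,
        pixel_size=block_mean.pixel_size,
        period=period,
        year=config.year,
    )
    return SyntheticScene(
        truth_fine=truth,
        observed_fine=observed,
        fine_mask=mask,
        coarse=coarse,
        period=CompositePeriod(year=config.year, index=period),
        config=config,
    )


def generate_year(config: SceneConfig) -> list[SyntheticScene]:
    """All composite periods of one synthetic year."""
    return [generate_scene(config, p) for p in range(1, config.n_periods + 1)]


def scene_pairs(
    scene: SyntheticScene, n_points: int | None = None, seed: int = 0
) -> PixelPairSet:
    """Clear-sky training pairs of a scene on the common fine grid.

    The coarse grid is replicated up to the fine grid (the method's default
    pairing direction) and pairs are taken where the observed fine grid is
    clear; optionally subsampled to ``n_points`` uniform random points.
    """
    factor = scene.truth_fine.shape[0] // scene.coarse.shape[0]
    coarse_up = resample_to_fine(scene.coarse, factor)
    pairs = extract_pairs(coarse_up, scene.observed_fine)
    if n_points is not None:
        pairs = sample_random_points(pairs, n_points, seed)
    return pairs
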