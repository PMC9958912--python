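"""Accuracy measures between predicted and reference NDVI.

Five indicators: RMSE and MAE for pixel differences; Pearson's r for linear
correlation; a scene-series efficiency coefficient
R = 1 - sum((X_i - Y_i)^2) / sum((Y_i - Ybar)^2) over per-scene means; PSNR
(dB) and SSIM for image quality.  RMSE/MAE/r/PSNR operate on flat value
sets restricted to jointly valid pixels; SSIM uses global image statistics
(means, variances, covariance) with the usual stabilizers c1 = (k1 L)^2,
c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, L the dynamic range (1.0 for NDVI in
[0, 1]).

Note the scene-series R is an efficiency coefficient (it can be negative and
is 1 only for exact agreement), not a correlation; Pearson's r is reported
separately so both readings of "R" are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .raster import GeometryError, RasterGrid

__all__ = [
    "MetricsReport",
    "rmse",
    "mae",
    "r_scene",
    "pearson_r",
    "psnr",
    "ssim",
    "evaluate",
]

SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _check_sets(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    r = np.asarray(ref, dtype=float).ravel()
    if p.shape != r.shape:
        raise ValueError(f"size mismatch: {p.shape} vs {r.shape}")
    if p.size == 0:
        raise ValueError("empty value sets")
    return p, r


def rmse(pred, ref) -> float:
    """Root mean square difference."""
    p, r = _check_sets(pred, ref)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def mae(pred, ref) -> float:
    """Mean absolute difference."""
    p, r = _check_sets(pred, ref)
    return float(np.mean(np.abs(p - r)))


def r_scene(pred_scene_means, ref_scene_means) -> float:
    """Efficiency coefficient over a series of per-scene means.

    1 - sum((X_i - Y_i)^2) / sum((Y_i - Ybar)^2), where X_i and Y_i are the
    predicted and reference scene means and Ybar is the reference series
    mean.  Requires a non-constant reference series of length >= 2.
    """
    x, y = _check_sets(pred_scene_means, ref_scene_means)
    if len(y) < 2:
        raise ValueError("scene series must have length >= 2")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0:
        raise ValueError("reference scene series is constant (degenerate denominator)")
    return float(1.0 - np.sum((x - y) ** 2) / denom)


def pearson_r(pred, ref) -> float:
    """Product-moment linear correlation coefficient."""
    p, r = _check_sets(pred, ref)
    if len(p) < 2:
        raise ValueError("correlation requires n >= 2")
    if np.std(p) == 0 or np.std(r) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(p, r)[0, 1])


def psnr(pred, ref) -> float:
    """Peak signal-to-noise ratio 10 log10(max_pred^2 / MSE), in dB.

    Identical inputs have zero MSE; that case is reported as ``math.inf``
    (the distinguished "identical" value).
    """
    p, r = _check_sets(pred, ref)
    mse = float(np.mean((p - r) ** 2))
    if mse == 0:
        return math.inf
    peak = float(np.max(p))
    if peak == 0:
        raise ValueError("degenerate PSNR: zero peak with nonzero MSE")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(pred, ref, dynamic_range: float = 1.0, as_printed: bool = False) -> float:
    """Structural similarity from global image statistics.

    Standard form:
        ((2 mu_p mu_t + c1)(2 cov + c2)) / ((mu_p^2 + mu_t^2 + c1)(var_p + var_t + c2))

    ``as_printed=True`` drops the ``+ c1`` in the first numerator factor (a
    variant that appears in some method descriptions); it no longer satisfies
    SSIM(x, x) = 1 for images with nonzero mean, so the standard form is the
    default.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise GeometryError(f"shape mismatch: {p.shape} vs {r.shape}")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be > 0")
    p, r = p.ravel(), r.ravel()
    c1 = (SSIM_K1 * dynamic_range) ** 2
    c2 = (SSIM_K2 * dynamic_range) ** 2
    mu_p, mu_r = p.mean(), r.mean()
    var_p, var_r = p.var(), r.var()
    cov = float(np.mean((p - mu_p) * (r - mu_r)))
    first = 2 * mu_p * mu_r if as_printed else 2 * mu_p * mu_r + c1
    return float(
        (first * (2 * cov + c2))
        / ((mu_p**2 + mu_r**2 + c1) * (var_p + var_r + c2))
    )


@dataclass
class MetricsReport:
    """All indicators between a predicted and a reference grid over one
    pixel support.  ``r_scene`` is populated only for series comparisons."""

    rmse: float
    mae: float
    r_pearson: float | None
    psnr: float
    ssim: float
    n_pixels: int
    support: str = "all-valid"
    r_scene: float | None = None

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "r_pearson": self.r_pearson,
            "r_scene": self.r_scene,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "n_pixels": self.n_pixels,
            "support": self.support,
        }


def evaluate(
    pred: RasterGrid,
    ref: RasterGrid,
    support: str = "all-valid",
    fill_mask: np.ndarray | None = None,
    dynamic_range: float = 1.0,
) -> MetricsReport:
    """All metrics over a selected pixel support.

    ``support`` is one of ``all-valid`` (every jointly valid pixel),
    ``filled-only`` (jointly valid pixels where ``fill_mask`` is set — the
    gap-filled pixels) or ``clear-only`` (its complement).
    """
    pred.require_same_geometry(ref)
    joint = ~pred.nodata & ~ref.nodata
    if support == "all-valid":
        sel = joint
    elif support in ("filled-only", "clear-only"):
        if fill_mask is None:
            raise ValueError(f"support {support!r} requires a fill_mask")
        fill_mask = np.asarray(fill_mask, dtype=bool)
        if fill_mask.shape != pred.shape:
            raise GeometryError("fill_mask shape mismatch")
        sel = joint & (fill_mask if support == "filled-only" else ~fill_mask)
    else:
        raise ValueError(f"unknown support {support!r}")
    if not sel.any():
        raise ValueError(f"empty support {support!r}")
    p, r = pred.values[sel], ref.values[sel]
    report = MetricsReport(
        rmse=rmse(p, r),
        mae=mae(p, r),
        r_pearson=(
            pearson_r(p, r) if len(p) >= 2 and np.std(p) > 0 and np.std(r) > 0 else None
        ),
        psnr=psnr(p, r),
        ssim=ssim(p, r, dynamic_range=dynamic_range),
        n_pixels=int(sel.sum()),
        support=support,
    )
    # Jensen: mean |d| <= sqrt(mean d^2) on any common sample.
    assert report.mae <= report.rmse + 1e-12
    return report
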