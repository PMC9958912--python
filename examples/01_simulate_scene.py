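"""Generate one synthetic coarse/fine NDVI scene pair and inspect it.

The generator builds a fine-resolution "truth" NDVI field from smoothed
land-cover patches with a mid-year seasonal peak, then derives what the two
sensors would see: a noisy fine observation with blob-shaped cloud/shadow
gaps, and a coarse counterpart equal to a monotone sensor distortion of the
block-mean truth plus independent noise.
"""

import numpy as np

import ndvigap as ng

config = ng.SceneConfig()  # 256x256 fine grid, factor 8, 30% clouds
scene = ng.generate_scene(config, period=12)  # mid-June composite window

masked = 1.0 - scene.fine_mask.is_clear().mean()
print(f"fine grid:   {scene.truth_fine.shape}, pixel {scene.truth_fine.pixel_size} m")
print(f"coarse grid: {scene.coarse.shape}, pixel {scene.coarse.pixel_size} m")
print(f"masked fraction (cloud+shadow): {masked:.3f}")
print(f"truth NDVI range: [{scene.truth_fine.values.min():.3f}, "
      f"{scene.truth_fine.values.max():.3f}]")

# the coarse value is a distorted block mean of the truth
block_mean = ng.aggregate_to_coarse(scene.truth_fine, config.factor)
resid = scene.coarse.values - config.distort(block_mean.values)
print(f"coarse minus g(block mean): std {np.std(resid):.4f} "
      f"(should be about the noise sigma, {config.noise_sigma})")

# Seasonal trajectory of the scene means across a year: rises to a mid-year
# peak and falls again, like cropland/forest NDVI.
means = [ng.generate_truth(config, p).values.mean() for p in range(1, 24)]
print("per-period mean NDVI:", " ".join(f"{m:.2f}" for m in means))
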