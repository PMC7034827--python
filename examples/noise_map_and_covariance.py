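"""Estimate a per-pixel noise map and propagate it through the pyramid.

Creates a field whose noise level differs between the left and right
halves (as it does between lung and mediastinum in a radiograph), shows
that the estimator recovers both levels, and prints the per-level
variance gains of the multi-scale noise covariance.
"""

import numpy as np

from radnoise import (NoiseMap, PyramidSpec, calibrate_band_gains,
                      estimate_noise_map, propagate_noise_covariance)

n = 192
gen = np.random.default_rng(3)
sigma_true = np.where(np.arange(n)[None, :] < n // 2, 0.01, 0.04)
field = 0.5 + gen.standard_normal((n, n)) * sigma_true

nm = estimate_noise_map(field, window=7)
left = np.median(nm.sigma[:, : n // 2 - 8])
right = np.median(nm.sigma[:, n // 2 + 8:])
print(f"true sigma: 0.010 | 0.040   estimated: {left:.4f} | {right:.4f}")

spec = PyramidSpec(n_levels=4)
gains = calibrate_band_gains(spec)
print("per-level white-noise variance gains:",
      " ".join(f"{g:.4f}" for g in gains[:4]))
cov = propagate_noise_covariance(nm, spec, gains)
for lvl, vmap in enumerate(cov.level_variance_maps):
    print(f"level {lvl}: variance map shape {vmap.shape}, "
          f"median band sigma {np.sqrt(np.median(vmap)):.5f}")
print("\nMost noise power lives in the finest band (gain ~0.9); the "
      "denoiser reads its local sigma per level from these maps.")
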