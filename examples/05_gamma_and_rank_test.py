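"""Gamma analysis under shifts/noise, and the rank-sum comparison test.

Shows what the two gamma criteria forgive and catch: a spatial shift is
absorbed by the 3-mm distance-to-agreement up to one voxel, and even strong
uncorrelated noise is largely rescued by the sub-voxel search, but a
systematic dose offset fails wherever the local gradient cannot compensate
for it. Then compares two metric samples with the Mann-Whitney U test.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from desire.dosimetry import GammaParams, gamma_pass_rate, mann_whitney_u
from desire.grids import VolumeGrid

rng = np.random.default_rng(0)
gt = VolumeGrid(gaussian_filter(rng.uniform(10, 70, (16, 16, 16)), 2.0),
                (2.5, 2.5, 2.5), "DOSE_GY")
interior = np.zeros(gt.shape, bool)
interior[2:-2, 2:-2, 2:-2] = True

for label, pred_vals in [
    ("identical", gt.values),
    ("1-voxel (2.5 mm) shift", np.roll(gt.values, 1, axis=2)),
    ("2-voxel (5 mm) shift", np.roll(gt.values, 2, axis=2)),
    ("+N(0, 1.5 Gy) noise", gt.values + rng.normal(0, 1.5, gt.shape)),
    ("systematic +3 Gy", gt.values + 3.0),
]:
    res = gamma_pass_rate(gt, gt.with_values(pred_vals), GammaParams(),
                          region_mask=interior)
    print(f"{label:24s}: pass rate {100 * res.pass_rate:6.2f}% "
          f"({res.n_evaluated} voxels)")
# the 2.5-mm shift passes fully (within the 3-mm DTA) and noise is rescued
# by the sub-voxel search; the uniform +3 Gy offset (> the 2.1 Gy criterion)
# fails wherever the dose gradient within 9 mm cannot make up 3 Gy

a = rng.normal(2.0, 0.8, 6)   # e.g. per-case MAEs of two models
b = rng.normal(3.0, 0.8, 6)
u, p = mann_whitney_u(a, b)
print(f"\nMann-Whitney U = {u:.1f}, two-sided p = {p:.4f} "
      f"({'significant' if p < 0.05 else 'not significant'} at 0.05)")
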