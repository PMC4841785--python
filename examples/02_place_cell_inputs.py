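"""Build place-cell inputs and verify the zero-mean property.

PCA-style learning needs zero-mean input.  A plain Gaussian place field is
positive everywhere, so the model uses difference-of-Gaussians
(centre-surround) fields whose spatial integral vanishes, or removes the
mean in time (temporal derivative / adaptation).
"""

import numpy as np

from gridfield import (
    ArenaConfig,
    PlaceEnsemble,
    adaptation_filter,
    generate_trajectory,
    stream_from_trajectory,
    temporal_derivative,
)

arena = ArenaConfig(side_length=100.0, grid_resolution=64)
ens = PlaceEnsemble.tiled(arena, cells_per_side=25, kind="dog", sigma1=3.9, sigma2=7.8)

raster = ens.rasters()[0]
print(f"cells                      : {ens.n_cells}")
print(f"DoG raster integral        : {raster.sum():+.2e}  (zero by construction)")
print(f"amplitude ratio c1/c2      : {ens.amplitudes[0] / ens.amplitudes[1]:.2f}"
      f"  (= (sigma2/sigma1)^2 = {(ens.sigma2 / ens.sigma1) ** 2:.0f} in 2D)")

traj = generate_trajectory(arena, steps=50_000, speed=1.0, seed=1)
stream = stream_from_trajectory(ens, traj)
print(f"stream shape [cells x T]   : {stream.activities.shape}")
print(f"max |temporal mean| (DoG)  : {np.abs(stream.activities.mean(axis=1)).max():.4f}")

diff = temporal_derivative(stream)
print(f"max |mean| after derivative: {np.abs(diff.activities.mean(axis=1)).max():.4f}")

psi = np.random.default_rng(0).uniform(0, 1, 100_000)
adapted = adaptation_filter(psi, delta=0.01)
print(f"adaptation output mean     : {adapted.mean():+.4f}  (zero asymptotically)")
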