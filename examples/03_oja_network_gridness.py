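"""Train the single-output Oja network with and without rectification.

With the non-negativity constraint (weights clipped at zero after every
update) the converged spatial projection is a hexagonal grid; without it,
a square-like pattern.  One run of each takes a few seconds.
"""

from gridfield import generate_trajectory, project_eigenvector, score_map, train
from gridfield.experiments import default_ensemble

ens = default_ensemble()  # 625 DoG cells, periodic arena of side 100

for constrained in (True, False):
    traj = generate_trajectory(ens.arena, steps=3_000_000, speed=1.0, seed=7)
    res = train(ens, traj, nonneg=constrained, seed=8)
    rate_map = project_eigenvector(res.J[0], ens)
    sc = score_map(rate_map, pixel_size=ens.arena.pixel_size)
    tag = "constrained  " if constrained else "unconstrained"
    print(f"{tag}: gridness60 = {sc.gridness60:+.2f}  gridness90 = {sc.gridness90:+.2f}"
          f"  spacing = {sc.spacing:.1f}")
# Expect gridness60 near 1 for the constrained run (hexagon) and a higher
# gridness90 than gridness60 for the unconstrained run (square).
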