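"""End-to-end experiment pipelines at the model's standard conditions.

Standard conditions (used throughout unless overridden): a periodic square
arena of side 100 tiled by 625 (25 x 25) difference-of-Gaussians place
cells with sigma1 = 3.9, sigma2 = 2 sigma1 = 7.8; an isotropic constant
speed random walk (speed 1 length unit/step, heading SD 0.2 rad/step); rate
maps rasterised at 64 x 64 pixels.  sigma1 = 3.9 puts the peak of the
tuning-curve transform nearest the fourfold axis orbit of the k-lattice, so
the leading eigenvalue group of the covariance is the well-separated group
of 4 (eigenvalue clusters of 4 and 8); with the theory-figure width 3.75
the fourfold and eightfold orbits are tied to within 2e-4, which blurs the
square structure of the unconstrained solutions.  Each pipeline derives
per-run seeds from a single master seed, so a (pipeline, seed) pair is
fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .arena import ArenaConfig, generate_trajectory
from .gridscore import GridScore, score_map, detect_modules
from .hebbian import LearningSchedule, train
from .ode import integrate_ode
from .pca import batch_pca, covariance_from_trajectory, exact_covariance, project_eigenvector
from .place import PlaceEnsemble
from .steady_state import SteadyStateProblem, solve_hierarchy, solve_steady_state

__all__ = [
    "default_arena",
    "default_ensemble",
    "derive_seeds",
    "network_experiment",
    "direct_pca_experiment",
    "nnpca_experiment",
    "ode_experiment",
    "spacing_sweep",
    "module_experiment",
]


def default_arena(side_length: float = 100.0, grid_resolution: int = 64) -> ArenaConfig:
    return ArenaConfig(side_length=side_length, boundary="periodic",
                       grid_resolution=grid_resolution)


def default_ensemble(arena: ArenaConfig | None = None, cells_per_side: int = 25,
                     sigma1: float = 3.9) -> PlaceEnsemble:
    arena = arena or default_arena()
    return PlaceEnsemble.tiled(arena, cells_per_side=cells_per_side, kind="dog",
                               sigma1=sigma1, sigma2=2.0 * sigma1)


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Independent child seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ----------------------------------------------------------------------


def network_experiment(
    n_runs: int = 20,
    constrained: bool = True,
    steps: int = 3_000_000,
    seed: int = 0,
    ensemble: PlaceEnsemble | None = None,
    speed: float = 1.0,
    turn_sd: float = 0.2,
    schedule: LearningSchedule | None = None,
) -> list[GridScore]:
    """Single-output Oja runs on difference-of-Gaussians inputs.

    Each run simulates a fresh random walk, trains the single-output
    network online (rectified after every step when ``constrained``),
    projects the converged weights onto place-cell space and scores the
    map.  Rate maps are scored on the arena raster.
    """
    ens = ensemble or default_ensemble()
    arena = ens.arena
    scores = []
    for s in derive_seeds(seed, n_runs):
        traj = generate_trajectory(arena, steps=steps, speed=speed, turn_sd=turn_sd,
                                   seed=int(s))
        res = train(ens, traj, n_outputs=1, nonneg=constrained, seed=int(s) + 1,
                    schedule=schedule)
        rate_map = project_eigenvector(res.J[0], ens)
        scores.append(score_map(rate_map, pixel_size=arena.pixel_size))
    return scores


def direct_pca_experiment(
    n_runs: int = 20,
    steps: int = 120_000,
    seed: int = 0,
    ensemble: PlaceEnsemble | None = None,
    speed: float = 1.0,
    turn_sd: float = 0.2,
) -> list[GridScore]:
    """Leading eigenvector of the sampled (mean-subtracted) covariance per
    trajectory, projected and scored.  The exact covariance is degenerate
    in multiples of 4; trajectory sampling noise picks one mixture of the
    leading eigenspace per run, giving the square-like unconstrained maps."""
    ens = ensemble or default_ensemble()
    arena = ens.arena
    scores = []
    for s in derive_seeds(seed, n_runs):
        traj = generate_trajectory(arena, steps=steps, speed=speed, turn_sd=turn_sd,
                                   seed=int(s))
        cov = covariance_from_trajectory(ens, traj)
        _, vecs = batch_pca(cov, k=1)
        rate_map = project_eigenvector(vecs[:, 0], ens)
        scores.append(score_map(rate_map, pixel_size=arena.pixel_size))
    return scores


def nnpca_experiment(
    n_runs: int = 20,
    seed: int = 0,
    arena: ArenaConfig | None = None,
    sigma1: float = 3.9,
    constrained: bool = True,
    max_iter: int = 5000,
    tol: float = 1e-10,
    return_solutions: bool = False,
):
    """Direct steady-state solves (FISTA-style) from random initialisations,
    scored on the projected output map psi = J * r.  Returns the scores, or
    ``(scores, solutions)`` when ``return_solutions`` is set."""
    arena = arena or default_arena()
    problem = SteadyStateProblem.for_dog(arena, sigma1=sigma1, sigma2=2.0 * sigma1,
                                         constraint="nonneg" if constrained else "none")
    scores, sols = [], []
    for s in derive_seeds(seed, n_runs):
        sol = solve_steady_state(problem, seed=int(s), max_iter=max_iter, tol=tol)
        sols.append(sol)
        scores.append(score_map(sol.projection(), pixel_size=arena.pixel_size))
    return (scores, sols) if return_solutions else scores


def ode_experiment(
    n_runs: int = 5,
    n_outputs: int = 40,
    constrained: bool = True,
    seed: int = 0,
    ensemble: PlaceEnsemble | None = None,
    max_steps: int = 20_000,
    tol: float = 1e-7,
) -> list[GridScore]:
    """Equilibria of dJ/dt = J Sigma - diag(J Sigma J^T) J from random unit
    initialisations (rows independent), using the exact uniform-occupancy
    covariance of the ensemble; each equilibrium row is projected and
    scored."""
    ens = ensemble or default_ensemble()
    sigma = exact_covariance(ens)
    n = ens.n_cells
    scores = []
    for s in derive_seeds(seed, n_runs):
        rng = np.random.default_rng(int(s))
        if constrained:
            J0 = rng.random((n_outputs, n))
        else:
            J0 = rng.standard_normal((n_outputs, n))
        J0 /= np.linalg.norm(J0, axis=1, keepdims=True)
        res = integrate_ode(sigma, J0, constrained=constrained, tol=tol,
                            max_steps=max_steps)
        for row in res.J:
            rate_map = project_eigenvector(row, ens)
            scores.append(score_map(rate_map, pixel_size=ens.arena.pixel_size))
    return scores


def spacing_sweep(
    sigmas=(4.0, 5.0, 6.0, 7.0, 8.0, 9.0),
    side_length: float = 500.0,
    grid_resolution: int = 256,
    seed: int = 0,
    max_iter: int = 4000,
    tol: float = 1e-10,
):
    """Grid spacing of the constrained steady-state solution versus place
    field width sigma (= sigma1, with sigma2 = 2 sigma1) in a fixed
    periodic arena; returns (slope, intercept, sigmas, spacings) of the
    least-squares line spacing = slope * sigma + intercept."""
    arena = ArenaConfig(side_length=side_length, boundary="periodic",
                        grid_resolution=grid_resolution)
    seeds = derive_seeds(seed, len(sigmas))
    spacings = []
    for sig, s in zip(sigmas, seeds):
        problem = SteadyStateProblem.for_dog(arena, sigma1=sig, sigma2=2.0 * sig,
                                             constraint="nonneg")
        sol = solve_steady_state(problem, seed=int(s), max_iter=max_iter, tol=tol)
        sc = score_map(sol.projection(), pixel_size=arena.pixel_size)
        spacings.append(sc.spacing)
    sigmas = np.asarray(sigmas, dtype=float)
    spacings = np.asarray(spacings)
    ok = np.isfinite(spacings)
    slope, intercept = np.polyfit(sigmas[ok], spacings[ok], 1)
    return float(slope), float(intercept), sigmas, spacings


def module_experiment(
    n_components: int = 100,
    seed: int = 0,
    arena: ArenaConfig | None = None,
    sigma1: float = 3.75,
    gridness_threshold: float = 0.7,
    max_iter: int = 5000,
):
    """Hierarchical (deflated) constrained solutions clustered into spacing
    modules; returns (scores, labels, centroid ratio)."""
    arena = arena or default_arena()
    problem = SteadyStateProblem.for_dog(arena, sigma1=sigma1, sigma2=2.0 * sigma1,
                                         constraint="nonneg")
    sols = solve_hierarchy(problem, n_components, seed=seed, max_iter=max_iter)
    scores = [score_map(s.projection(), pixel_size=arena.pixel_size) for s in sols]
    spacings = np.array([sc.spacing for sc in scores])
    gridness = np.array([sc.gridness60 for sc in scores])
    labels, ratio = detect_modules(spacings, gridness, gridness_threshold)
    return scores, labels, ratio
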