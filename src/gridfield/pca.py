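"""Batch PCA of the place-cell covariance and spatial projection of weights.

Under periodic boundaries and a uniformly tiled ensemble the covariance is
circulant (every row a cyclic shift of the first), so its eigenvectors are
discrete sinusoids; the leading eigenspace is degenerate in multiples of 4
by square-box symmetry, which is why unconstrained solutions come out as
square-ish mixtures of plane waves.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg

from .arena import ArenaConfig, Trajectory
from .place import InputStream, PlaceEnsemble

__all__ = [
    "covariance_from_stream",
    "covariance_from_trajectory",
    "exact_covariance",
    "batch_pca",
    "project_eigenvector",
]


def covariance_from_stream(stream: InputStream) -> np.ndarray:
    """Mean-subtracted second-moment matrix (1/T) sum (r_t - rbar)(r_t - rbar)^T."""
    R = stream.activities
    if R.shape[1] <= 1:
        raise ValueError("need more than one time step for a covariance")
    Rc = R - R.mean(axis=1, keepdims=True)
    return (Rc @ Rc.T) / R.shape[1]


def covariance_from_trajectory(
    ensemble: PlaceEnsemble,
    traj: Trajectory,
    chunk: int = 20_000,
) -> np.ndarray:
    """Covariance accumulated in trajectory chunks (avoids materialising the
    full [Neuron x Time] matrix for long walks)."""
    n = ensemble.n_cells
    T = len(traj)
    if T <= 1:
        raise ValueError("need more than one time step for a covariance")
    s = np.zeros(n)
    ss = np.zeros((n, n))
    for lo in range(0, T, chunk):
        R = ensemble.eval(traj.positions[lo : lo + chunk])
        s += R.sum(axis=1)
        ss += R @ R.T
    mean = s / T
    return ss / T - np.outer(mean, mean)


def exact_covariance(ensemble: PlaceEnsemble) -> np.ndarray:
    """Covariance under exactly uniform occupancy: spatial averages of
    r_i(x) r_j(x) over the arena raster, mean-subtracted."""
    G = ensemble.arena.grid_resolution
    R = ensemble.rasters().reshape(ensemble.n_cells, G * G)
    Rc = R - R.mean(axis=1, keepdims=True)
    return (Rc @ Rc.T) / (G * G)


def batch_pca(sigma: np.ndarray, k: int | None = None):
    """Top-k eigenpairs of a symmetric covariance, eigenvalues descending.

    Returns ``(eigenvalues, eigenvectors)`` with orthonormal eigenvectors in
    the columns.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8 * max(1.0, np.abs(sigma).max())):
        raise ValueError("covariance must be symmetric")
    n = sigma.shape[0]
    k = n if k is None else min(k, n)
    vals, vecs = linalg.eigh(sigma, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def project_eigenvector(q: np.ndarray, ensemble: PlaceEnsemble) -> np.ndarray:
    """Spatial rate map Phi(x) = sum_j q_j r_j(x) on the arena raster."""
    q = np.asarray(q, dtype=float).ravel()
    if len(q) != ensemble.n_cells:
        raise ValueError("weight vector length must equal the number of cells")
    G = ensemble.arena.grid_resolution
    R = ensemble.rasters().reshape(ensemble.n_cells, G * G)
    return (q @ R).reshape(G, G)
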