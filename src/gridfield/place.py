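"""Place-cell tuning curves, input streams, and zero-mean preprocessing.

Three tuning-curve shapes are supported:

* ``gaussian`` — a plain 2D Gaussian bump, value 1 at the centre.  Has a
  positive spatial mean, so a network fed with it does not perform PCA on
  zero-mean data (and does not produce grids) unless the stream is
  differentiated in time or the output is adaptation-filtered.
* ``dog`` — difference of Gaussians (centre-surround / Mexican hat):
  ``c1 exp(-|x|^2 / 2 sigma1^2) - c2 exp(-|x|^2 / 2 sigma2^2)`` with the
  amplitudes chosen so that each cell's discrete spatial integral over the
  arena raster is exactly zero.  In 2D the infinite-plane condition is
  ``c1 sigma1^2 = c2 sigma2^2``; the constants here are computed numerically
  on the raster so the discrete zero-mean is exact.
* ``disk`` — a positive inner circle surrounded by a negative ring, the
  ring amplitude solving the zero-integral condition analytically.

Centres tile the arena uniformly on a square lattice by default (one cell
per raster pixel of the tiling resolution), matching the assumption that
the number of place cells equals the number of image pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaConfig, Trajectory

__all__ = [
    "PlaceEnsemble",
    "InputStream",
    "disk_outer_amplitude",
    "eval_tuning",
    "stream_from_trajectory",
    "temporal_derivative",
    "adaptation_filter",
]


def disk_outer_amplitude(r_inner: float, r_outer: float, inner_amplitude: float = 1.0) -> float:
    """Ring amplitude making a positive-disk / negative-ring field integrate to zero.

    Solving ``a_in * pi r^2 + a_out * pi (R^2 - r^2) = 0`` for ``a_out``.
    """
    if not 0 < r_inner < r_outer:
        raise ValueError("need 0 < r_inner < r_outer")
    return -inner_amplitude * r_inner**2 / (r_outer**2 - r_inner**2)


@dataclass
class PlaceEnsemble:
    """A population of identical tuning curves on a square lattice of centres."""

    arena: ArenaConfig
    centers: np.ndarray  # (n, 2)
    kind: str = "dog"  # gaussian | dog | disk
    sigma1: float = 3.75
    sigma2: float = 7.5  # dog: surround width; disk: outer radius
    amplitudes: tuple[float, float] | None = None  # (c1, c2); None = auto zero-mean

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.kind not in ("gaussian", "dog", "disk"):
            raise ValueError(f"unknown tuning kind {self.kind!r}")
        if self.kind == "dog" and not (self.sigma2 > self.sigma1 > 0):
            raise ValueError("dog tuning needs sigma2 > sigma1 > 0 (else identically zero)")
        if self.kind == "disk" and not (self.sigma2 > self.sigma1 > 0):
            raise ValueError("disk tuning needs outer radius sigma2 > inner radius sigma1 > 0")
        if self.amplitudes is None:
            self.amplitudes = self._zero_mean_amplitudes()

    # -- construction -----------------------------------------------------

    @classmethod
    def tiled(
        cls,
        arena: ArenaConfig,
        cells_per_side: int = 25,
        kind: str = "dog",
        sigma1: float = 3.75,
        sigma2: float = 7.5,
    ) -> "PlaceEnsemble":
        """Centres on a uniform ``cells_per_side``² square lattice."""
        step = arena.side_length / cells_per_side
        coords = (np.arange(cells_per_side) + 0.5) * step
        cx, cy = np.meshgrid(coords, coords, indexing="xy")
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        ens = cls(arena=arena, centers=centers, kind=kind, sigma1=sigma1, sigma2=sigma2)
        ens._tile_coords = coords  # marks the separable square-lattice layout
        return ens

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def _zero_mean_amplitudes(self) -> tuple[float, float]:
        """(c1, c2) with c1 = 1 and c2 balancing the discrete raster integral."""
        if self.kind == "gaussian":
            return (1.0, 0.0)
        if self.kind == "disk":
            # c2 stores the (negative) ring value itself
            return (1.0, disk_outer_amplitude(self.sigma1, self.sigma2))
        # dog: balance the two Gaussians on the arena raster (periodic:
        # minimum-image distances) so the discrete sum is exactly zero.
        d2 = self._sq_dist_to_raster(self.centers[:1])[0]
        g1 = np.exp(-d2 / (2.0 * self.sigma1**2)).sum()
        g2 = np.exp(-d2 / (2.0 * self.sigma2**2)).sum()
        return (1.0, g1 / g2)

    # -- evaluation -------------------------------------------------------

    def _sq_displacement(self, points: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Squared distances (n_centers, n_points), minimum-image if periodic."""
        diff = points[None, :, :] - centers[:, None, :]
        if self.arena.boundary == "periodic":
            L = self.arena.side_length
            diff = diff - L * np.round(diff / L)
        return np.einsum("cpd,cpd->cp", diff, diff)

    def _sq_dist_to_raster(self, centers: np.ndarray) -> np.ndarray:
        G = self.arena.grid_resolution
        px = self.arena.pixel_size
        coords = (np.arange(G) + 0.5) * px
        xx, yy = np.meshgrid(coords, coords, indexing="xy")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        return self._sq_displacement(pts, centers)

    def eval(self, points: np.ndarray) -> np.ndarray:
        """Activity matrix (n_cells, n_points) at the given positions."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = self._sq_displacement(points, self.centers)
        c1, c2 = self.amplitudes
        if self.kind == "gaussian":
            return np.exp(-d2 / (2.0 * self.sigma1**2))
        if self.kind == "dog":
            return c1 * np.exp(-d2 / (2.0 * self.sigma1**2)) - c2 * np.exp(
                -d2 / (2.0 * self.sigma2**2)
            )
        # disk: piecewise-constant positive core / negative ring
        out = np.zeros_like(d2)
        out[d2 <= self.sigma1**2] = c1
        ring = (d2 > self.sigma1**2) & (d2 <= self.sigma2**2)
        out[ring] = c2
        return out

    def rasters(self) -> np.ndarray:
        """All cells evaluated on the arena raster, shape (n_cells, G, G).

        Cached: the raster is reused by every weight projection.
        """
        cached = getattr(self, "_raster_cache", None)
        if cached is not None:
            return cached
        G = self.arena.grid_resolution
        d2 = self._sq_dist_to_raster(self.centers)
        c1, c2 = self.amplitudes
        if self.kind == "gaussian":
            vals = np.exp(-d2 / (2.0 * self.sigma1**2))
        elif self.kind == "dog":
            vals = c1 * np.exp(-d2 / (2.0 * self.sigma1**2)) - c2 * np.exp(
                -d2 / (2.0 * self.sigma2**2)
            )
        else:
            vals = np.zeros_like(d2)
            vals[d2 <= self.sigma1**2] = c1
            vals[(d2 > self.sigma1**2) & (d2 <= self.sigma2**2)] = c2
        self._raster_cache = vals.reshape(self.n_cells, G, G)
        return self._raster_cache


def eval_tuning(ensemble: PlaceEnsemble, x) -> np.ndarray:
    """Activity vector (one value per cell) at position ``x``."""
    return ensemble.eval(np.atleast_2d(x))[:, 0]


@dataclass
class InputStream:
    """[Neuron x Time] activity matrix with its preprocessing tag."""

    activities: np.ndarray  # (n_cells, T)
    preprocessing: str = "raw"  # raw | temporal_derivative | adaptation

    def __post_init__(self) -> None:
        self.activities = np.asarray(self.activities, dtype=float)
        if self.activities.ndim != 2:
            raise ValueError("activities must be (n_cells, T)")

    @property
    def n_cells(self) -> int:
        return self.activities.shape[0]

    @property
    def n_steps(self) -> int:
        return self.activities.shape[1]


def stream_from_trajectory(ensemble: PlaceEnsemble, traj: Trajectory) -> InputStream:
    """Evaluate every cell along the trajectory; column t is the activity at X(t)."""
    if len(traj) < 1:
        raise ValueError("empty trajectory")
    return InputStream(activities=ensemble.eval(traj.positions), preprocessing="raw")


def temporal_derivative(stream: InputStream) -> InputStream:
    """First temporal difference Δr(t) = r(t+1) - r(t); zero-mean for isotropic walks."""
    if stream.n_steps < 2:
        raise ValueError("temporal derivative needs at least 2 time steps")
    return InputStream(
        activities=np.diff(stream.activities, axis=1),
        preprocessing="temporal_derivative",
    )


def adaptation_filter(psi: np.ndarray, delta: float, initial_mean: float = 0.0) -> np.ndarray:
    """Running-average subtraction: psi_t - psibar_t with
    psibar_t = (1 - delta) psibar_{t-1} + delta psi_t.

    ``delta`` in (0, 1] weighs the present sample; delta = 1 returns zeros,
    delta -> 0+ returns the raw series.  For i.i.d. input the output mean
    tends to zero.  Works on the last axis of an arbitrary array.
    """
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    psi = np.asarray(psi, dtype=float)
    # psibar_t = (1-d)^t psibar_0 + d * sum_{s<=t} (1-d)^(t-s) psi_s — use
    # the recursive form for numerical stability at small delta.
    out = np.empty_like(psi)
    bar = np.full(psi.shape[:-1], initial_mean, dtype=float)
    for t in range(psi.shape[-1]):
        bar = (1.0 - delta) * bar + delta * psi[..., t]
        out[..., t] = psi[..., t] - bar
    return out
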