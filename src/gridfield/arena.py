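"""Square arena geometry and the agent's random-walk trajectory.

The model assumes an agent performing an ergodic, isotropic random walk in a
square box ``S = [0, L)^2``.  Under periodic boundary conditions time
averages of the place-cell activity can be replaced by uniform space
averages, which is what the steady-state theory relies on; the trajectory
simulator here is deliberately minimal (constant speed, diffusing heading)
and makes no attempt at realistic rodent kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaConfig",
    "Trajectory",
    "generate_trajectory",
    "occupancy_map",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Square arena of side ``side_length`` with a boundary convention.

    Parameters
    ----------
    side_length
        Side of the box, in arbitrary length units.  Must be positive.
    boundary
        ``"periodic"`` (positions wrap modulo L; tuning curves use
        minimum-image distances) or ``"zero"`` (walls; the walk reflects).
    grid_resolution
        Number of pixels per side used for every spatial raster derived
        from this arena (rate maps, occupancy, steady-state solutions).
    """

    side_length: float = 100.0
    boundary: str = "periodic"
    grid_resolution: int = 64

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError(f"side_length must be > 0, got {self.side_length}")
        if self.boundary not in ("periodic", "zero"):
            raise ValueError(f"boundary must be 'periodic' or 'zero', got {self.boundary!r}")
        if self.grid_resolution < 8:
            raise ValueError(f"grid_resolution must be >= 8, got {self.grid_resolution}")

    @property
    def pixel_size(self) -> float:
        return self.side_length / self.grid_resolution

    def wrap(self, xy: np.ndarray) -> np.ndarray:
        """Map positions into [0, L).  Idempotent.  Periodic arenas only.

        np.mod can round a tiny negative input up to exactly L; fold that
        edge case back to 0 so the [0, L) contract holds.
        """
        w = np.mod(xy, self.side_length)
        return np.where(w >= self.side_length, 0.0, w)


@dataclass
class Trajectory:
    """Time-indexed positions of the agent inside the arena."""

    positions: np.ndarray  # (T, 2), inside [0, L)^2
    dt: float = 1.0
    speed: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (T, 2)")
        if len(self.positions) < 1:
            raise ValueError("trajectory must contain at least one position")

    def __len__(self) -> int:
        return len(self.positions)

    def save(self, path) -> None:
        """Write as 3-column delimited text (t, x, y)."""
        t = np.arange(len(self)) * self.dt
        np.savetxt(
            path,
            np.column_stack([t, self.positions]),
            header="t x y",
            fmt="%.8g",
        )

    @classmethod
    def load(cls, path, dt: float = 1.0) -> "Trajectory":
        data = np.atleast_2d(np.loadtxt(path))
        return cls(positions=data[:, 1:3], dt=dt)


def generate_trajectory(
    arena: ArenaConfig,
    steps: int,
    speed: float = 1.0,
    turn_sd: float = 0.2,
    seed: int = 0,
    start: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate an isotropic constant-speed random walk.

    The heading performs a Gaussian random walk (standard deviation
    ``turn_sd`` radians per step) starting from a uniformly random
    direction, so no direction is preferred by construction.  Periodic
    arenas wrap positions modulo L; zero-boundary arenas reflect at the
    walls.

    Parameters
    ----------
    steps
        Number of positions returned (the start position counts).
    speed
        Distance travelled per step, in arena length units.
    turn_sd
        Standard deviation of the per-step heading increment, radians.
    seed
        Seed for the trajectory's private random stream.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    if speed < 0:
        raise ValueError(f"speed must be >= 0, got {speed}")
    rng = np.random.default_rng(seed)
    L = arena.side_length

    if start is None:
        pos0 = rng.uniform(0.0, L, size=2)
    else:
        pos0 = np.asarray(start, dtype=float)
    heading0 = rng.uniform(0.0, 2.0 * np.pi)
    turns = rng.normal(0.0, turn_sd, size=steps - 1)
    headings = heading0 + np.cumsum(turns)

    free = np.empty((steps, 2))
    free[0] = pos0
    free[1:, 0] = pos0[0] + np.cumsum(speed * np.cos(headings))
    free[1:, 1] = pos0[1] + np.cumsum(speed * np.sin(headings))

    if arena.boundary == "periodic":
        out = np.mod(free, L)
    else:
        # A walk reflected at the walls is the image of the free walk under
        # the fold map x -> L - |x mod 2L - L| (each bounce flips the
        # velocity component, which is exactly what folding does).
        out = L - np.abs(np.mod(free, 2.0 * L) - L)
    return Trajectory(positions=out, dt=1.0, speed=speed, seed=seed)


def occupancy_map(traj: Trajectory, arena: ArenaConfig) -> np.ndarray:
    """Raster of visit counts; shape (G, G), sums to len(traj)."""
    G = arena.grid_resolution
    L = arena.side_length
    ix = np.clip((traj.positions[:, 0] / L * G).astype(int), 0, G - 1)
    iy = np.clip((traj.positions[:, 1] / L * G).astype(int), 0, G - 1)
    counts = np.zeros((G, G))
    np.add.at(counts, (iy, ix), 1)
    return counts
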