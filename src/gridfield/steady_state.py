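"""Direct solution of the (non-negative) PCA steady-state problem.

In the limit of a dense, uniform place-cell ensemble and an ergodic walk,
the variance of a linear output becomes a convolution objective over the
weight field J(x) on the arena:

    maximise   (1/|S|) int (J * r)^2 dx
    subject to (1/|S|) int J^2 dx = 1   (and J >= 0 when constrained)

with r the common tuning kernel (zero spatial mean).  On a periodic raster
the objective is ``sum_k |J_hat(k)|^2 |r_hat(k)|^2``, the gradient is a
single FFT convolution, and the exact Lipschitz constant of the gradient is
``2 max_k |r_hat(k)|^2``, so an accelerated projected-gradient method (a
FISTA scheme with hard constraints and no shrinkage) needs no tuning.  The
feasible-set projection alternates clipping at zero with renormalisation.
Without the constraint the same iteration converges to the Fourier optimum
(the leading eigenvector of the circulant covariance operator).

Successive components are obtained by deflation: each accepted solution's
projection is removed from the kernel operator, after which re-solving
yields the next constrained 'eigenvector'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaConfig
from .place import PlaceEnsemble

__all__ = [
    "SteadyStateProblem",
    "SteadyStateSolution",
    "tuning_kernel",
    "solve_steady_state",
    "deflate",
    "solve_hierarchy",
]


def tuning_kernel(arena: ArenaConfig, kind: str = "dog", sigma1: float = 3.75,
                  sigma2: float = 7.5) -> np.ndarray:
    """Tuning curve rasterised about the origin of the periodic raster.

    The kernel is shifted to exact zero spatial sum (the PCA objective is
    only meaningful for zero-mean kernels).
    """
    ens = PlaceEnsemble(
        arena=arena, centers=np.array([[0.0, 0.0]]), kind=kind,
        sigma1=sigma1, sigma2=sigma2,
    )
    k = ens.rasters()[0]
    return k - k.mean()


@dataclass
class SteadyStateProblem:
    """Convolution objective on a periodic raster, optionally deflated."""

    arena: ArenaConfig
    kernel: np.ndarray  # (G, G) zero-sum tuning kernel about the origin
    constraint: str = "nonneg"  # none | nonneg
    deflated: list = field(default_factory=list)  # previous solution rasters

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        G = self.arena.grid_resolution
        if self.kernel.shape != (G, G):
            raise ValueError("kernel raster must match arena grid_resolution")
        if self.constraint not in ("none", "nonneg"):
            raise ValueError("constraint must be 'none' or 'nonneg'")
        if abs(self.kernel.sum()) > 1e-6 * np.abs(self.kernel).sum():
            raise ValueError("kernel must have zero spatial sum")

    @classmethod
    def for_dog(cls, arena: ArenaConfig, sigma1: float = 3.75, sigma2: float = 7.5,
                constraint: str = "nonneg") -> "SteadyStateProblem":
        return cls(arena=arena, kernel=tuning_kernel(arena, "dog", sigma1, sigma2),
                   constraint=constraint)

    # -- operator pieces ---------------------------------------------------

    @property
    def n_pix(self) -> int:
        return self.kernel.size

    def power_spectrum(self) -> np.ndarray:
        """|r_hat(k)|^2 with r_hat = FFT(kernel) / n_pix."""
        return np.abs(np.fft.fft2(self.kernel)) ** 2 / self.n_pix**2

    def _deflate_apply(self, v: np.ndarray, transpose: bool = False) -> np.ndarray:
        """(I - pi_1)...(I - pi_n) applied right-to-left (or its transpose)."""
        comps = self.deflated if transpose else list(reversed(self.deflated))
        for J in comps:
            v = v - J * (np.vdot(J, v).real / self.n_pix)
        return v

    def objective(self, J: np.ndarray) -> float:
        """sum_k |(D J)_hat|^2 |r_hat|^2 under hats = FFT / n_pix."""
        v = self._deflate_apply(J)
        w = self.power_spectrum()
        Jhat2 = np.abs(np.fft.fft2(v)) ** 2 / self.n_pix**2
        return float(np.sum(Jhat2 * w))

    def gradient(self, J: np.ndarray) -> np.ndarray:
        w = self.power_spectrum()
        v = self._deflate_apply(J)
        g = np.fft.ifft2(w * np.fft.fft2(v)).real * (2.0 / self.n_pix)
        return self._deflate_apply(g, transpose=True)

    def lipschitz(self) -> float:
        return float(2.0 * self.power_spectrum().max() / self.n_pix)

    def project(self, J: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Projection onto the feasible set: clip (if constrained), then sphere."""
        if self.constraint == "nonneg":
            J = np.maximum(J, 0.0)
        nrm = np.linalg.norm(J)
        if nrm == 0.0:
            if rng is None:
                raise ValueError("cannot project the zero field")
            J = rng.random(J.shape)
            nrm = np.linalg.norm(J)
        return J * (np.sqrt(self.n_pix) / nrm)

    def convolve(self, J: np.ndarray) -> np.ndarray:
        """Output field psi = J * r (the spatial projection of the weights),
        with the (1/n_pix) quadrature of the mean-over-arena convention."""
        return np.fft.ifft2(np.fft.fft2(J) * np.fft.fft2(self.kernel)).real / self.n_pix


@dataclass
class SteadyStateSolution:
    """A locally optimal weight field and its optimisation trace."""

    J: np.ndarray  # (G, G), (1/n_pix) sum J^2 = 1; J >= 0 if constrained
    objective_trace: np.ndarray  # accepted (non-decreasing) objective values
    converged: bool
    n_iter: int
    problem: SteadyStateProblem

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def projection(self) -> np.ndarray:
        """Spatial output map psi = J * r, the analogue of projecting
        converged weights onto place-cell space."""
        return self.problem.convolve(self.J)


def solve_steady_state(
    problem: SteadyStateProblem,
    seed: int = 0,
    max_iter: int = 50_000,
    tol: float = 1e-9,
    J0: np.ndarray | None = None,
) -> SteadyStateSolution:
    """Accelerated projected gradient ascent on the convolution objective.

    Monotone FISTA: a momentum (Nesterov) candidate is accepted only when it
    improves the objective, otherwise momentum restarts from the best
    iterate, so the recorded objective trace is non-decreasing.  Step size
    is 1/L with the analytic Lipschitz constant; convergence is declared
    when the relative objective change over an acceptance falls below
    ``tol``.
    """
    rng = np.random.default_rng(seed)
    G = problem.arena.grid_resolution
    if J0 is None:
        J0 = rng.random((G, G)) if problem.constraint == "nonneg" else rng.standard_normal((G, G))
    x = problem.project(np.asarray(J0, dtype=float), rng)
    step = 1.0 / problem.lipschitz()

    y = x.copy()
    t = 1.0
    f_x = problem.objective(x)
    trace = [f_x]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = problem.project(y + step * problem.gradient(y), rng)
        f_z = problem.objective(z)
        if f_z >= f_x:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            y = z + ((t - 1.0) / t_next) * (z - x)
            rel = (f_z - f_x) / max(f_x, 1e-300)
            x, f_x, t = z, f_z, t_next
            trace.append(f_x)
            if rel < tol and it > 100:
                converged = True
                break
        else:
            # momentum overshoot: restart from the best point
            y = x.copy()
            t = 1.0
            if np.allclose(problem.project(x + step * problem.gradient(x), rng), x, atol=1e-12):
                converged = True
                break
    return SteadyStateSolution(
        J=x, objective_trace=np.array(trace), converged=converged,
        n_iter=it, problem=problem,
    )


def fourier_table(solution: SteadyStateSolution, n_top: int = 32) -> np.ndarray:
    """Strongest Fourier components of a solution as rows (k_x, k_y, |J_hat|).

    Wavevectors are in physical units (2 pi m / L); conjugate pairs both
    appear.  Useful for inspecting the lattice structure of a solution.
    """
    J = solution.J
    G = J.shape[0]
    L = solution.problem.arena.side_length
    Jhat = np.abs(np.fft.fft2(J)) / J.size
    freq = np.fft.fftfreq(G) * G * 2.0 * np.pi / L
    ky, kx = np.meshgrid(freq, freq, indexing="ij")
    flat = np.column_stack([kx.ravel(), ky.ravel(), Jhat.ravel()])
    return flat[np.argsort(-flat[:, 2])][:n_top]


def deflate(problem: SteadyStateProblem, solutions) -> SteadyStateProblem:
    """Problem whose operator has the given unit-norm solutions projected out."""
    rasters = [
        s.J if isinstance(s, SteadyStateSolution) else np.asarray(s, dtype=float)
        for s in solutions
    ]
    for J in rasters:
        nrm2 = np.sum(J * J) / problem.n_pix
        if abs(nrm2 - 1.0) > 1e-6:
            raise ValueError("deflation components must satisfy (1/n_pix) sum J^2 = 1")
    return SteadyStateProblem(
        arena=problem.arena, kernel=problem.kernel,
        constraint=problem.constraint,
        deflated=list(problem.deflated) + rasters,
    )


def solve_hierarchy(
    problem: SteadyStateProblem,
    n_components: int,
    seed: int = 0,
    max_iter: int = 20_000,
    tol: float = 1e-9,
) -> list[SteadyStateSolution]:
    """Successive components via solve-then-deflate, mirroring the
    hierarchical (Sanger-like) multi-output scheme."""
    sols: list[SteadyStateSolution] = []
    prob = problem
    seeds = np.random.SeedSequence(seed).generate_state(n_components)
    for i in range(n_components):
        sol = solve_steady_state(prob, seed=int(seeds[i] % (2**31)), max_iter=max_iter, tol=tol)
        sols.append(sol)
        prob = deflate(prob, [sol])
    return sols
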