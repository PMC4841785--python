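"""Online Hebbian learning: the Oja rule and its hierarchical (Sanger) form.

A single linear output trained with the self-normalising Oja update

    dJ_i = eps_t (psi r_i - psi^2 J_i),   psi = f(J . r)

converges, for zero-mean inputs, to the principal eigenvector of the input
covariance with ||J|| -> 1.  The multi-output generalisation subtracts the
back-projection of earlier outputs (Gram-Schmidt-like), so output i learns
the i-th component:

    dJ_ij = eps_t (r_j psi_i - psi_i sum_{k<=i} J_kj psi_k)

Non-negativity is imposed, when requested, by rectifying the weights after
every update; that single change turns the learned spatial projections from
square-like into hexagonal grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Trajectory
from .place import InputStream, PlaceEnsemble, adaptation_filter

__all__ = [
    "output_activity",
    "oja_step",
    "sanger_step",
    "LearningSchedule",
    "TrainResult",
    "train",
]

try:  # compiled fast path for the long single-output online runs
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an ordinary dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=False)
def _oja_dog_tiled(
    xs, ys, cx, cy, s1, s2, c1, c2, L, periodic,
    J, eps0, t0, nonneg, seed, record_every, norm_out, delta_out,
):
    """End-to-end single-output Oja training on a square-lattice DoG ensemble.

    Exploits the separability of each Gaussian: per step only the per-axis
    factors exp(-dx^2/2 sigma^2) are evaluated (O(sqrt(n)) exps) and the
    cell activity r_ij = c1 gx1_i gy1_j - c2 gx2_i gy2_j is formed inside
    the update.  J is (n_cy, n_cx), updated in place.  Returns a status
    code: 0 ok, 2 norm divergence.
    """
    np.random.seed(seed)
    nx = cx.shape[0]
    ny = cy.shape[0]
    gx1 = np.empty(nx)
    gx2 = np.empty(nx)
    gy1 = np.empty(ny)
    gy2 = np.empty(ny)
    inv1 = 1.0 / (2.0 * s1 * s1)
    inv2 = 1.0 / (2.0 * s2 * s2)
    acc = 0.0
    n = nx * ny
    rec = 0
    for t in range(xs.shape[0]):
        x = xs[t]
        y = ys[t]
        for i in range(nx):
            d = x - cx[i]
            if periodic:
                d -= L * np.round(d / L)
            gx1[i] = np.exp(-d * d * inv1)
            gx2[i] = np.exp(-d * d * inv2)
        for j in range(ny):
            d = y - cy[j]
            if periodic:
                d -= L * np.round(d / L)
            gy1[j] = np.exp(-d * d * inv1)
            gy2[j] = np.exp(-d * d * inv2)
        psi = 0.0
        for j in range(ny):
            a1 = 0.0
            a2 = 0.0
            for i in range(nx):
                a1 += J[j, i] * gx1[i]
                a2 += J[j, i] * gx2[i]
            psi += c1 * gy1[j] * a1 - c2 * gy2[j] * a2
        eps = eps0 / (1.0 + t / t0)
        p2 = psi * psi
        d_acc = 0.0
        nrm2 = 0.0
        allzero = True
        for j in range(ny):
            b1 = c1 * gy1[j]
            b2 = c2 * gy2[j]
            for i in range(nx):
                r = b1 * gx1[i] - b2 * gx2[i]
                dj = eps * (psi * r - p2 * J[j, i])
                v = J[j, i] + dj
                if nonneg and v < 0.0:
                    v = 0.0
                J[j, i] = v
                d_acc += abs(dj)
                nrm2 += v * v
                if v != 0.0:
                    allzero = False
        acc += d_acc / n
        if nrm2 > 100.0:
            return 2
        if allzero:
            s = 0.0
            for j in range(ny):
                for i in range(nx):
                    J[j, i] = np.random.random()
                    s += J[j, i] * J[j, i]
            s = np.sqrt(s)
            for j in range(ny):
                for i in range(nx):
                    J[j, i] /= s
        if (t + 1) % record_every == 0 and rec < norm_out.shape[0]:
            norm_out[rec] = np.sqrt(nrm2)
            delta_out[rec] = acc / record_every
            acc = 0.0
            rec += 1
    return 0


@_njit(cache=False)
def _oja_chunk(J, RT, eps_arr, nonneg, use_tanh, delta, psibar0):
    """In-place single-output Oja updates over one chunk.

    RT is (steps, n) with one input sample per row.  Returns
    (sum of mean|dJ| per step, final psibar, status) with status 1 when a
    rectified row died (all zeros; caller re-initialises) and 2 on norm
    divergence.
    """
    n = J.shape[0]
    psibar = psibar0
    acc = 0.0
    for c in range(RT.shape[0]):
        r = RT[c]
        psi = 0.0
        for i in range(n):
            psi += J[i] * r[i]
        if use_tanh:
            psi = np.tanh(psi)
        if delta > 0.0:
            psibar = (1.0 - delta) * psibar + delta * psi
            psi = psi - psibar
        eps = eps_arr[c]
        p2 = psi * psi
        d = 0.0
        nrm2 = 0.0
        allzero = True
        for i in range(n):
            dj = eps * (psi * r[i] - p2 * J[i])
            v = J[i] + dj
            if nonneg and v < 0.0:
                v = 0.0
            d += abs(dj)
            J[i] = v
            nrm2 += v * v
            if v != 0.0:
                allzero = False
        acc += d / n
        if allzero:
            return acc, psibar, 1, c + 1
        if nrm2 > 100.0:
            return acc, psibar, 2, c + 1
    return acc, psibar, 0, RT.shape[0]


def _activate(x, activation: str):
    if activation == "linear":
        return x
    if activation == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {activation!r}")


def output_activity(J: np.ndarray, r: np.ndarray, activation: str = "linear") -> np.ndarray:
    """psi = f(J . r); J may be a single weight vector or an (outputs, inputs) matrix."""
    J = np.asarray(J, dtype=float)
    r = np.asarray(r, dtype=float)
    if J.shape[-1] != r.shape[0]:
        raise ValueError("weight/input dimension mismatch")
    return _activate(J @ r, activation)


def oja_step(
    J: np.ndarray,
    r: np.ndarray,
    eps: float,
    nonneg: bool = False,
    activation: str = "linear",
) -> np.ndarray:
    """One Oja update J' = J + eps (psi r - psi^2 J), rectified if ``nonneg``."""
    if eps <= 0:
        raise ValueError("learning rate must be > 0")
    if not (np.all(np.isfinite(J)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite weights or inputs")
    psi = output_activity(J, r, activation)
    J_new = J + eps * (psi * r - psi**2 * J)
    if nonneg:
        J_new = np.maximum(J_new, 0.0)
    return J_new


def sanger_step(
    J: np.ndarray,
    r: np.ndarray,
    eps: float,
    nonneg: bool = False,
    activation: str = "linear",
) -> np.ndarray:
    """One hierarchical update; with a single output this is exactly Oja."""
    if eps <= 0:
        raise ValueError("learning rate must be > 0")
    J = np.atleast_2d(np.asarray(J, dtype=float))
    if not (np.all(np.isfinite(J)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite weights or inputs")
    psi = output_activity(J, r, activation)  # (k,)
    back = np.tril(np.outer(psi, psi)) @ J  # row i: psi_i sum_{k<=i} psi_k J_k
    J_new = J + eps * (np.outer(psi, r) - back)
    if nonneg:
        J_new = np.maximum(J_new, 0.0)
    return J_new


@dataclass(frozen=True)
class LearningSchedule:
    """eps_t = eps0 / (1 + t / t0): satisfies sum eps = inf, sum eps^2 < inf."""

    eps0: float = 0.05
    t0: float = 1e5

    def __call__(self, t) -> np.ndarray:
        return self.eps0 / (1.0 + np.asarray(t, dtype=float) / self.t0)


@dataclass
class TrainResult:
    """Converged weights and training diagnostics."""

    J: np.ndarray  # (outputs, inputs)
    norm_history: np.ndarray  # row norms sampled every ``record_every`` steps
    delta_history: np.ndarray  # windowed mean |dJ| per entry
    converged: bool
    steps_run: int

    @property
    def weights(self) -> np.ndarray:
        """Single-output convenience view."""
        return self.J[0] if self.J.shape[0] == 1 else self.J


def save_weights(path, result: TrainResult, **metadata) -> None:
    """Checkpoint converged weights as delimited text with a metadata header."""
    header = " ".join(f"{k}={v}" for k, v in metadata.items())
    np.savetxt(path, result.J, header=f"{header} steps={result.steps_run}", fmt="%.10g")


def load_weights(path) -> np.ndarray:
    """Weights matrix (outputs, inputs) from a checkpoint file."""
    return np.atleast_2d(np.loadtxt(path))


def weights_from_map(rate_map: np.ndarray, ensemble: PlaceEnsemble,
                     rectify: bool = False) -> np.ndarray:
    """Initial weights encoding a spatial pattern: the projection of the map
    onto each cell's tuning curve, optionally rectified, unit-normalised.

    Used to start the network from shaped initial conditions (stripes,
    squares, noisy hexagons) in stability experiments.
    """
    G = ensemble.arena.grid_resolution
    m = np.asarray(rate_map, dtype=float)
    if m.shape != (G, G):
        raise ValueError("map raster must match the arena grid_resolution")
    R = ensemble.rasters().reshape(ensemble.n_cells, G * G)
    q = R @ m.ravel() / (G * G)
    if rectify:
        q = np.maximum(q, 0.0)
    nrm = np.linalg.norm(q)
    if nrm == 0:
        raise ValueError("map projects to the zero weight vector")
    return q / nrm


def train(
    source,
    traj: Trajectory | None = None,
    n_outputs: int = 1,
    nonneg: bool = False,
    activation: str = "linear",
    schedule: LearningSchedule | None = None,
    preprocessing: str = "raw",
    adaptation_delta: float | None = None,
    seed: int = 0,
    record_every: int = 1000,
    conv_tol: float = 0.0,
    chunk: int = 10_000,
    J0: np.ndarray | None = None,
) -> TrainResult:
    """Online training of the (possibly rectified) Hebbian network.

    Parameters
    ----------
    source
        Either an :class:`InputStream` or a :class:`PlaceEnsemble` (in which
        case ``traj`` must be given and activities are evaluated lazily in
        chunks along the trajectory).
    preprocessing
        ``"raw"`` or ``"temporal_derivative"`` (first temporal difference of
        the activities; makes the stream zero-mean for isotropic walks).
    adaptation_delta
        If set, the output psi is passed through the running-average
        subtraction filter with this delta before entering the update
        (temporal zero-mean enforced on the output side).
    conv_tol
        Early stop when the windowed mean per-entry |dJ| drops below this;
        0 disables early stopping (the full stream is consumed).
    J0
        Optional initial weights (outputs, inputs), e.g. from
        :func:`weights_from_map`; default random unit rows.

    Raises
    ------
    RuntimeError
        If any weight row norm exceeds 10 (divergence).
    """
    rng = np.random.default_rng(seed)
    schedule = schedule or LearningSchedule()
    if preprocessing not in ("raw", "temporal_derivative"):
        raise ValueError(f"unknown preprocessing {preprocessing!r}")

    if isinstance(source, InputStream):
        n_in = source.n_cells
        total = source.n_steps

        def chunks():
            for lo in range(0, total, chunk):
                yield source.activities[:, lo : lo + chunk]

    elif isinstance(source, PlaceEnsemble):
        if traj is None:
            raise ValueError("a trajectory is required when training from an ensemble")
        n_in = source.n_cells
        total = len(traj)

        def chunks():
            for lo in range(0, total, chunk):
                yield source.eval(traj.positions[lo : lo + chunk])

    else:
        raise TypeError("source must be an InputStream or a PlaceEnsemble")

    if J0 is not None:
        J = np.atleast_2d(np.asarray(J0, dtype=float)).copy()
        if J.shape != (n_outputs, n_in):
            raise ValueError("J0 shape must be (n_outputs, n_inputs)")
    else:
        # uniform(0,1) init, each row normalised to unit norm
        J = rng.random((n_outputs, n_in))
        J /= np.linalg.norm(J, axis=1, keepdims=True)
    single = n_outputs == 1

    # fully compiled path for the standard long runs: single linear output,
    # raw stream from a square-lattice difference-of-Gaussians ensemble
    coords = getattr(source, "_tile_coords", None)
    if (
        _HAVE_NUMBA
        and single
        and coords is not None
        and isinstance(source, PlaceEnsemble)
        and source.kind == "dog"
        and traj is not None
        and activation == "linear"
        and adaptation_delta is None
        and preprocessing == "raw"
        and isinstance(schedule, LearningSchedule)
    ):
        nxy = len(coords)
        J2d = J[0].reshape(nxy, nxy)
        n_rec = total // record_every
        norm_out = np.zeros(n_rec)
        delta_out = np.zeros(n_rec)
        c1, c2 = source.amplitudes
        status = _oja_dog_tiled(
            np.ascontiguousarray(traj.positions[:, 0]),
            np.ascontiguousarray(traj.positions[:, 1]),
            np.asarray(coords), np.asarray(coords),
            source.sigma1, source.sigma2, c1, c2,
            source.arena.side_length, source.arena.boundary == "periodic",
            J2d, schedule.eps0, schedule.t0, nonneg,
            int(rng.integers(2**31)), record_every, norm_out, delta_out,
        )
        if status == 2:
            raise RuntimeError("weight norm diverged (norm > 10)")
        done = conv_tol == 0.0 or bool(delta_out.size and delta_out[-1] < conv_tol)
        return TrainResult(
            J=J, norm_history=norm_out[:, None], delta_history=delta_out,
            converged=done, steps_run=total,
        )

    psibar = np.zeros(n_outputs)
    norms, deltas = [], []
    acc_delta, acc_count = 0.0, 0
    t = 0
    converged = False
    prev_col = None
    for R in chunks():
        if preprocessing == "temporal_derivative":
            first = prev_col is None
            if first:
                prev_col = R[:, :1]
            R_use = np.diff(np.concatenate([prev_col, R], axis=1), axis=1)
            prev_col = R[:, -1:]
            if first:  # drop the artificial first difference
                R_use = R_use[:, 1:]
            if R_use.shape[1] == 0:
                continue
        else:
            R_use = R
        n_cols = R_use.shape[1]
        eps_arr = schedule(t + np.arange(n_cols))
        if single:
            RT = np.ascontiguousarray(R_use.T)
            acc, pb, status, used = _oja_chunk(
                J[0], RT, eps_arr, nonneg, activation == "tanh",
                adaptation_delta if adaptation_delta is not None else 0.0,
                psibar[0],
            )
            psibar[0] = pb
            t += used
            if status == 2:
                raise RuntimeError(f"weight norm diverged at step {t}")
            if status == 1:  # rectification zeroed the whole vector
                J[0] = rng.random(n_in)
                J[0] /= np.linalg.norm(J[0])
            acc_delta += acc
            acc_count += used
            nrm = np.linalg.norm(J, axis=1)
            norms.append(nrm.copy())
            deltas.append(acc_delta / max(acc_count, 1))
            acc_delta, acc_count = 0.0, 0
            if conv_tol > 0 and deltas[-1] < conv_tol:
                converged = True
                break
            continue
        for c in range(n_cols):
            r = R_use[:, c]
            eps = eps_arr[c]
            psi = _activate(J @ r, activation)
            if adaptation_delta is not None:
                psibar = (1 - adaptation_delta) * psibar + adaptation_delta * psi
                psi = psi - psibar
            dJ = eps * (np.outer(psi, r) - np.tril(np.outer(psi, psi)) @ J)
            J = J + dJ
            if nonneg:
                np.maximum(J, 0.0, out=J)
                dead = ~J.any(axis=1)
                if dead.any():
                    J[dead] = rng.random((int(dead.sum()), n_in))
                    J[dead] /= np.linalg.norm(J[dead], axis=1, keepdims=True)
            acc_delta += np.abs(dJ).mean()
            acc_count += 1
            t += 1
            if t % record_every == 0:
                nrm = np.linalg.norm(J, axis=1)
                if np.any(nrm > 10.0):
                    raise RuntimeError(
                        f"weight norm diverged (max {nrm.max():.3g} at step {t})"
                    )
                norms.append(nrm.copy())
                deltas.append(acc_delta / max(acc_count, 1))
                acc_delta, acc_count = 0.0, 0
                if conv_tol > 0 and deltas[-1] < conv_tol:
                    converged = True
                    break
        if converged:
            break
    if conv_tol == 0.0:
        converged = True  # ran the full stream as requested
    return TrainResult(
        J=np.atleast_2d(J),
        norm_history=np.array(norms) if norms else np.empty((0, n_outputs)),
        delta_history=np.array(deltas),
        converged=converged,
        steps_run=t,
    )
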