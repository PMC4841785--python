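"""Averaged (ODE) dynamics of the Hebbian network and its equilibria.

Stochastic-approximation theory replaces the random Oja/Sanger recurrence
by its associated deterministic ODE

    dJ/dt = J Sigma - diag(J Sigma J^T) J

whose equilibria satisfy J Sigma = diag(J Sigma J^T) J: every normalised
eigenvector of Sigma is a fixed point, but only the principal one is
stable.  Rows of J evolve independently, so a run with many outputs is a
batch of independent 1-output flows.  The non-negativity constraint is
imposed, as in the network, by an entrywise cut-off applied between
integration steps (projected integration); rows are not renormalised — the
flow itself drives row norms to 1 at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OdeResult", "equilibrium_residual", "integrate_ode"]


def equilibrium_residual(J: np.ndarray, sigma: np.ndarray) -> float:
    """Frobenius norm of J Sigma - diag(J Sigma J^T) J (0 at equilibria)."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    JS = J @ sigma
    lam = np.einsum("ij,ij->i", JS, J)
    return float(np.linalg.norm(JS - lam[:, None] * J))


@dataclass
class OdeResult:
    J: np.ndarray  # (outputs, n) equilibrium estimate
    residual: float
    converged: bool
    n_steps: int


def integrate_ode(
    sigma: np.ndarray,
    J0: np.ndarray,
    constrained: bool = False,
    tol: float = 1e-8,
    max_steps: int = 20_000,
    dt: float | None = None,
) -> OdeResult:
    """Integrate the averaged weight dynamics to an equilibrium.

    Explicit Euler steps of size ``dt`` (default 0.2 / lambda_max(Sigma), a
    stable step for this flow since J stays bounded near the unit sphere)
    with the entrywise cut-off at zero applied after every step in the
    constrained case.  Terminates when the residual per row drops below
    ``tol`` (unconstrained) or when the per-step weight change per unit
    flow time drops below ``tol`` (constrained, where the residual of the
    free flow need not vanish on the face of the constraint set).
    """
    sigma = np.asarray(sigma, dtype=float)
    J = np.atleast_2d(np.asarray(J0, dtype=float)).copy()
    if J.shape[1] != sigma.shape[0]:
        raise ValueError("J0 and Sigma dimensions disagree")
    lam_max = np.linalg.eigvalsh(sigma)[-1]
    h = (0.2 / lam_max) if dt is None else dt

    def rhs(J):
        JS = J @ sigma
        lam = np.einsum("ij,ij->i", JS, J)
        return JS - lam[:, None] * J

    n = 0
    converged = False
    for n in range(1, max_steps + 1):
        F = rhs(J)
        J_new = J + h * F
        if constrained:
            np.maximum(J_new, 0.0, out=J_new)
        change = np.abs(J_new - J).max()
        J = J_new
        if constrained:
            if change / h < tol * lam_max:
                converged = True
                break
        else:
            if float(np.linalg.norm(rhs(J))) < tol * np.sqrt(J.shape[0]):
                converged = True
                break
    return OdeResult(J=J, residual=float(np.linalg.norm(rhs(J))), converged=converged, n_steps=n)
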