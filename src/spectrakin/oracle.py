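"""Independent brute-force references used by the test suite.

None of these share a code path with what they certify: the ODE reference
integrates the homogeneous kinetics with a high-order implicit scipy solver,
the diffusion reference is a Crank-Nicolson finite-difference scheme on a
fine grid, and the quadrature is composite Gauss-Legendre.  Tolerances here
are kept roughly two orders tighter than the assertions that consume them.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import splu

from .kinetics import ReactionNetwork, reaction_term

__all__ = ["ode_reference", "fd_diffusion_reference", "quadrature"]


def ode_reference(
    network: ReactionNetwork,
    rho0: ArrayLike,
    t_end: float,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> NDArray[np.float64]:
    """Homogeneous kinetics rho(t_end) by adaptive implicit integration."""
    rho0 = np.asarray(rho0, float)
    if t_end == 0:
        return rho0.copy()
    sol = solve_ivp(
        lambda t, y: reaction_term(network, y),
        (0.0, t_end),
        rho0,
        method="Radau",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    return sol.y[:, -1]


def fd_diffusion_reference(
    profile: Callable[[NDArray], NDArray],
    D: float,
    bc: tuple[str, str],
    t_end: float,
    *,
    domain: tuple[float, float] = (0.0, 1.0),
    resolution: int = 2000,
    n_steps: int = 2000,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Crank-Nicolson solution of the 1D heat equation with the given BCs.

    ``profile`` is evaluated on the fine node grid for the initial data.
    Dirichlet ends pin the nodal value to zero; Neumann ends use a ghost-node
    reflection (second-order).  Returns (x, rho(t_end)).
    """
    a, b = domain
    x = np.linspace(a, b, resolution + 1)
    h = (b - a) / resolution
    u = np.asarray(profile(x), float).copy()
    n = x.size
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    A = sparse.diags([off, main, off], [-1, 0, 1], format="lil")
    for side, idx, nb in ((bc[0], 0, 1), (bc[1], n - 1, n - 2)):
        if side == "dirichlet":
            A[idx, :] = 0.0
            u[idx] = 0.0
        elif side == "neumann":
            A[idx, :] = 0.0
            A[idx, idx] = -2.0
            A[idx, nb] = 2.0
        else:
            raise ValueError(f"unknown BC {side!r}")
    Lap = (D / h**2) * A.tocsc()
    dt = t_end / n_steps
    I = sparse.identity(n, format="csc")
    lhs = splu((I - 0.5 * dt * Lap).tocsc())
    rhs = (I + 0.5 * dt * Lap).tocsc()
    for _ in range(n_steps):
        u = lhs.solve(rhs @ u)
    return x, u


def quadrature(
    f: Callable[[NDArray], NDArray],
    domain: tuple[float, float],
    weight: Callable[[NDArray], NDArray] | None = None,
    *,
    n_panels: int = 200,
    order: int = 12,
) -> float:
    """Composite Gauss-Legendre integral of f (optionally times a weight)."""
    a, b = domain
    nodes, wts = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(a, b, n_panels + 1)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        x = mid + half * nodes
        y = np.asarray(f(x), float)
        if weight is not None:
            y = y * np.asarray(weight(x), float)
        total += half * float(wts @ y)
    return total
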