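"""Reaction networks and the Kahan reaction time step.

A network of zeroth-, first- and second-order mass-action reactions defines
a quadratic vector field ``R(rho) = M @ v(rho)`` where ``M`` is the constant
stoichiometric matrix (products minus reactants, species x reactions) and
``v`` contains one monomial per reaction.  The Jacobian ``J_R = M @ dv/drho``
is assembled analytically from the monomial exponents.

The reaction step uses Kahan's method,

.. math:: \\rho' = \\rho + \\Delta t\\,[I - \\tfrac{\\Delta t}{2} J_R(\\rho)]^{-1} R(\\rho),

an A-stable, linearly implicit, second-order one-step scheme that needs one
small dense linear solve per grid point and no nonlinear iteration.  For the
scalar Riccati flow ``drho/dt = -k rho^2`` it reproduces the exact solution
``rho0 / (1 + k rho0 t)``, and it preserves every linear invariant
``w.T @ rho`` with ``w.T @ M = 0`` exactly.

Rate-constant units in the package system: order 0 — Species nm^-1 ns^-1
(film) or nm^-3 ns^-1 (radial); order 1 — ns^-1; order 2 — nm ns^-1 (film)
or nm^3 ns^-1 (radial), all per Species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "KahanStepError",
    "rate_vector",
    "reaction_term",
    "jacobian",
    "kahan_step",
]


@dataclass(frozen=True)
class Species:
    """A chemical species with its diffusion coefficient (nm^2 ns^-1)."""

    name: str
    diffusion_coefficient: float = 0.0
    initial_profile: dict | None = None

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError(f"negative diffusion coefficient for {self.name}")


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction of order 0, 1 or 2.

    The A + A convention: the rate monomial is ``v = k * rho_A**2`` and each
    event removes two A (stoichiometry -2), so tables that quote the observed
    ``d[A]/dt = -2k[A]^2`` constant should be imported with the loader flag
    ``aa_convention = halve``.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if self.rate_constant < 0:
            raise ValueError(f"negative rate constant in reaction {self.label or self}")
        if len(self.reactants) > 2:
            raise ValueError("only zeroth, first and second order reactions are supported")

    @property
    def order(self) -> int:
        return len(self.reactants)


class KahanStepError(RuntimeError):
    """Singular Kahan linear system; carries the grid point index and dt."""

    def __init__(self, point: int, dt: float):
        self.point = point
        self.dt = dt
        super().__init__(
            f"singular Kahan system at grid point {point} with dt={dt!r}; "
            "the adaptive controller should halve dt"
        )


class ReactionNetwork:
    """Species list, reactions, stoichiometric matrix and monomial exponents.

    Attributes
    ----------
    M : ndarray, shape (S, Q)
        Integer stoichiometric matrix, products minus reactants per column.
    exponents : ndarray, shape (Q, S)
        Monomial exponent of each species in each reaction rate.
    """

    def __init__(self, species: Sequence[Species], reactions: Iterable[Reaction]):
        self.species = list(species)
        self.reactions = list(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        self.index = {name: i for i, name in enumerate(names)}
        S, Q = len(self.species), len(self.reactions)
        self.M = np.zeros((S, Q), dtype=int)
        self.exponents = np.zeros((Q, S), dtype=int)
        for q, rxn in enumerate(self.reactions):
            for name in rxn.reactants:
                i = self._lookup(name, rxn)
                self.M[i, q] -= 1
                self.exponents[q, i] += 1
            for name in rxn.products:
                i = self._lookup(name, rxn)
                self.M[i, q] += 1
        self.rate_constants = np.array([r.rate_constant for r in self.reactions], float)
        self.diffusion_coefficients = np.array(
            [s.diffusion_coefficient for s in self.species], float
        )

    def _lookup(self, name: str, rxn: Reaction) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise KeyError(
                f"reaction {rxn.label or rxn} references undeclared species {name!r}"
            ) from None

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def with_reactions(self, extra: Iterable[Reaction]) -> "ReactionNetwork":
        """A new network with additional reactions (e.g. dose-rate sources)."""
        return ReactionNetwork(self.species, self.reactions + list(extra))

    def scaled_second_order(self, factor: float) -> "ReactionNetwork":
        """A copy with all second-order rate constants multiplied by factor.

        Used to convert volumetric (nm^3/ns) constants to the 1D-column
        (nm/ns) system given a cross-section in nm^2.
        """
        rxns = [
            replace(r, rate_constant=r.rate_constant * factor) if r.order == 2 else r
            for r in self.reactions
        ]
        return ReactionNetwork(self.species, rxns)

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, {self.n_reactions} reactions)"
        )


def rate_vector(network: ReactionNetwork, concentrations: ArrayLike) -> NDArray[np.float64]:
    """Mass-action rates, one per reaction.

    ``v_q = k_q * prod_s rho_s**e_qs``; supports batched input with species
    on the last axis.
    """
    rho = np.asarray(concentrations, dtype=float)
    # prod over species of rho**e; exponent matrix is tiny, so explicit loop
    # over reactions is clearer than a log-space trick and safe at rho = 0.
    v = np.broadcast_to(network.rate_constants, rho.shape[:-1] + (network.n_reactions,)).copy()
    for q in range(network.n_reactions):
        for s in np.nonzero(network.exponents[q])[0]:
            e = network.exponents[q, s]
            v[..., q] *= rho[..., s] ** e
    return v


def reaction_term(network: ReactionNetwork, concentrations: ArrayLike) -> NDArray[np.float64]:
    """Net production rate per species, ``R = M @ v``."""
    v = rate_vector(network, concentrations)
    return v @ network.M.T.astype(float)


def jacobian(network: ReactionNetwork, concentrations: ArrayLike) -> NDArray[np.float64]:
    """Analytic Jacobian ``J_R = M @ dv/drho`` (batched; species last axis)."""
    rho = np.asarray(concentrations, dtype=float)
    Q, S = network.exponents.shape
    dv = np.zeros(rho.shape[:-1] + (Q, S))
    for q in range(Q):
        for s in np.nonzero(network.exponents[q])[0]:
            e = network.exponents[q, s]
            term = float(network.rate_constants[q]) * e * rho[..., s] ** (e - 1)
            for s2 in np.nonzero(network.exponents[q])[0]:
                if s2 != s:
                    term = term * rho[..., s2] ** network.exponents[q, s2]
            dv[..., q, s] = term
    return np.einsum("ij,...jk->...ik", network.M.astype(float), dv)


def kahan_step(
    network: ReactionNetwork, concentrations: ArrayLike, dt: float
) -> NDArray[np.float64]:
    """One Kahan step of the homogeneous kinetics at each grid point.

    Accepts shape ``(S,)`` or ``(P, S)``; the P point problems are
    independent, so the linear solves are batched.  Raises
    :class:`KahanStepError` on a singular system (caller halves dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rho = np.asarray(concentrations, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("non-finite concentrations")
    R = reaction_term(network, rho)
    J = jacobian(network, rho)
    S = network.n_species
    A = np.broadcast_to(np.eye(S), J.shape).copy() - (dt / 2.0) * J
    try:
        y = np.linalg.solve(A, R[..., None])[..., 0]
    except np.linalg.LinAlgError:
        if A.ndim == 2:
            raise KahanStepError(0, dt) from None
        for p in range(A.shape[0]):  # locate the offending point for diagnostics
            try:
                np.linalg.solve(A[p], R[p])
            except np.linalg.LinAlgError:
                raise KahanStepError(p, dt) from None
        raise
    return rho + dt * y
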