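"""Small synthetic networks and analytic profiles for tests and examples.

Everything here is generated in memory — no data files, no downloads — so
the core solver can be exercised end to end with closed-form expectations.
The random constructors take an explicit seeded generator; the solver itself
contains no randomness.
"""

from __future__ import annotations

import numpy as np

from .kinetics import Reaction, ReactionNetwork, Species

__all__ = [
    "decay_network",
    "riccati_network",
    "ab_to_c_network",
    "three_species_nonlinear",
    "source_sink_network",
    "pure_source_network",
    "zero_network",
    "random_network",
    "gaussian",
]


def zero_network(species_names=("A",), D=(0.0,)) -> ReactionNetwork:
    """Species with no reactions at all (pure diffusion)."""
    return ReactionNetwork(
        [Species(n, d) for n, d in zip(species_names, D)], []
    )


def decay_network(k: float = 1.0, D: float = 0.0) -> ReactionNetwork:
    """First-order decay A -> (nothing tracked)."""
    return ReactionNetwork([Species("A", D)], [Reaction(("A",), (), k)])


def riccati_network(k: float = 1.0) -> ReactionNetwork:
    """Scalar quadratic decay d[A]/dt = -k[A]^2 via A+A -> A.

    One molecule lost per event with rate k*rho^2; the exact flow is
    rho0 / (1 + k rho0 t), which the Kahan step reproduces exactly.
    """
    return ReactionNetwork([Species("A")], [Reaction(("A", "A"), ("A",), k)])


def ab_to_c_network(k: float = 1.0, D=(0.0, 0.0, 0.0)) -> ReactionNetwork:
    sp = [Species(n, d) for n, d in zip("ABC", D)]
    return ReactionNetwork(sp, [Reaction(("A", "B"), ("C",), k)])


def three_species_nonlinear() -> ReactionNetwork:
    """A stiff-ish nonlinear 3-species cycle used for order measurements."""
    sp = [Species("A"), Species("B"), Species("C")]
    rxns = [
        Reaction(("A", "B"), ("C",), 1.3),
        Reaction(("C",), ("A",), 0.7),
        Reaction(("A", "A"), ("B",), 0.4),
        Reaction((), ("A",), 0.2),
    ]
    return ReactionNetwork(sp, rxns)


def source_sink_network(S: float = 1.0, k: float = 1.0, D: float = 0.0) -> ReactionNetwork:
    """Constant source plus first-order sink; fixed point rho* = S/k."""
    return ReactionNetwork(
        [Species("A", D)],
        [Reaction((), ("A",), S), Reaction(("A",), (), k)],
    )


def pure_source_network(S: float, D: float) -> ReactionNetwork:
    """Uniform zeroth-order source, no chemistry (the thin-film toy).

    With a Dirichlet sink at x=0 and a Neumann wall at x=L the steady state
    is rho(x) = (S/D)(L x - x^2/2), so the boundary value is S L^2 / (2 D).
    """
    return ReactionNetwork([Species("A", D)], [Reaction((), ("A",), S)])


def random_network(
    rng: np.random.Generator, n_species: int = 4, n_reactions: int = 6
) -> ReactionNetwork:
    """A random mass-action network (orders 0-2) for property tests."""
    names = [f"S{i}" for i in range(n_species)]
    species = [Species(n, float(rng.uniform(0, 2))) for n in names]
    rxns = []
    for q in range(n_reactions):
        order = int(rng.integers(0, 3))
        reactants = tuple(rng.choice(names, size=order, replace=True))
        products = tuple(rng.choice(names, size=int(rng.integers(0, 3)), replace=True))
        rxns.append(Reaction(reactants, products, float(rng.uniform(0.1, 2.0)), label=f"r{q}"))
    return ReactionNetwork(species, rxns)


def gaussian(center: float, sigma: float, amplitude: float = 1.0):
    """Callable 1D Gaussian profile for initial conditions and oracles."""
    return lambda x: amplitude * np.exp(-((np.asarray(x) - center) ** 2) / (2 * sigma**2))
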