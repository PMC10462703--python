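"""Boundary-condition-respecting trigonometric bases and spectral fields.

A concentration profile on an interval ``[x0, x1]`` (or a radial shell
``[a, b]``) is expanded as a linear combination of ``N + 1`` basis functions

.. math:: \\rho(x, t) = \\sum_{n=0}^{N} c_n(t)\\, \\phi_n(x),

where every :math:`\\phi_n` satisfies the boundary conditions of the problem
individually, so any linear combination does too.  Four interval families are
supported (sine/cosine with each Dirichlet/Neumann end pairing) together with
a spherically symmetric radial family
:math:`\\phi_n(r) = \\sin(\\omega_n (r - a)) / r`, which reduces the radial
diffusion operator to the interval one acting on :math:`u = r\\rho`.

Dirichlet means the concentration is pinned to zero (a perfect sink, e.g. a
chemically absorbing oxide surface); Neumann means zero net flux (e.g. a
water-headspace boundary at transfer equilibrium).

Units follow the package convention: lengths in nm, time in ns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


class BasisKind(str, enum.Enum):
    SINE = "sine"
    COSINE = "cosine"
    RADIAL_SINE = "radial-sine"


class BC(str, enum.Enum):
    DIRICHLET = "dirichlet"
    NEUMANN = "neumann"


#: The (kind, bc_left, bc_right) combinations with a defined frequency rule.
#: Interval rows mirror the four classical sine/cosine end-condition pairings;
#: the radial family applies the sine rules to u = r*rho on (r - a).
_SUPPORTED = {
    (BasisKind.SINE, BC.DIRICHLET, BC.NEUMANN),
    (BasisKind.COSINE, BC.NEUMANN, BC.DIRICHLET),
    (BasisKind.SINE, BC.DIRICHLET, BC.DIRICHLET),
    (BasisKind.COSINE, BC.NEUMANN, BC.NEUMANN),
    (BasisKind.RADIAL_SINE, BC.DIRICHLET, BC.DIRICHLET),
    (BasisKind.RADIAL_SINE, BC.DIRICHLET, BC.NEUMANN),
}


@dataclass(frozen=True)
class Basis:
    """A trigonometric basis on an interval or radial shell.

    ``N + 1`` usable modes are exposed through a contiguous 0-based index
    ``n = 0..N``.  For the Dirichlet-Dirichlet sine family the ``n = 0``
    function of the textbook indexing is identically zero, so modes are
    stored internally as ``n' = n + 1``; callers only ever see the exposed
    index, whose frequency is ``frequencies[n]``.
    """

    kind: BasisKind
    bc_left: BC
    bc_right: BC
    domain_start: float
    domain_end: float
    N: int
    frequencies: NDArray[np.float64] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.frequencies is None:
            object.__setattr__(self, "frequencies", _frequencies(self))
        object.__setattr__(self, "frequencies", np.asarray(self.frequencies, float))

    @property
    def L(self) -> float:
        """Domain length (nm)."""
        return self.domain_end - self.domain_start

    @property
    def n_modes(self) -> int:
        return self.N + 1

    @property
    def is_radial(self) -> bool:
        return self.kind is BasisKind.RADIAL_SINE

    @property
    def half_integer(self) -> bool:
        """True for the families with frequencies (pi/L)(n + 1/2)."""
        return self.bc_left != self.bc_right if not self.is_radial else (
            self.bc_right is BC.NEUMANN
        )


def _frequencies(basis: Basis) -> NDArray[np.float64]:
    L = basis.domain_end - basis.domain_start
    n = np.arange(basis.N + 1, dtype=float)
    key = (basis.kind, basis.bc_left, basis.bc_right)
    if key in {(BasisKind.SINE, BC.DIRICHLET, BC.NEUMANN),
               (BasisKind.COSINE, BC.NEUMANN, BC.DIRICHLET),
               (BasisKind.RADIAL_SINE, BC.DIRICHLET, BC.NEUMANN)}:
        return (np.pi / L) * (n + 0.5)
    if key in {(BasisKind.SINE, BC.DIRICHLET, BC.DIRICHLET),
               (BasisKind.RADIAL_SINE, BC.DIRICHLET, BC.DIRICHLET)}:
        return (np.pi / L) * (n + 1.0)  # internal shift: zero mode dropped
    if key == (BasisKind.COSINE, BC.NEUMANN, BC.NEUMANN):
        return (np.pi / L) * n
    raise AssertionError(key)


def make_basis(
    kind: BasisKind | str,
    bc_left: BC | str,
    bc_right: BC | str,
    domain_start: float,
    domain_end: float,
    N: int,
) -> Basis:
    """Construct a basis with frequencies filled per its family rule.

    Parameters
    ----------
    kind
        ``"sine"``, ``"cosine"`` or ``"radial-sine"``.
    bc_left, bc_right
        ``"dirichlet"`` (zero concentration, perfect sink) or ``"neumann"``
        (zero flux).  For the radial family the left condition is the
        regularity/Dirichlet condition on ``u = r*rho`` at the inner radius.
    domain_start, domain_end
        Domain limits in nm; ``domain_end > domain_start >= 0`` is required
        for the radial family.
    N
        Highest exposed mode index; the basis carries ``N + 1`` modes.
    """
    kind = BasisKind(kind)
    bc_left = BC(bc_left)
    bc_right = BC(bc_right)
    if not domain_end > domain_start:
        raise ValueError(f"domain_end ({domain_end}) must exceed domain_start ({domain_start})")
    if N < 0:
        raise ValueError("N must be >= 0")
    if kind is BasisKind.RADIAL_SINE and domain_start < 0:
        raise ValueError("radial-sine requires domain_start >= 0")
    if (kind, bc_left, bc_right) not in _SUPPORTED:
        raise ValueError(
            f"unsupported basis family {kind.value}/{bc_left.value}-{bc_right.value}; "
            "supported: sine dirichlet-neumann, cosine neumann-dirichlet, "
            "sine dirichlet-dirichlet, cosine neumann-neumann, and "
            "radial-sine with dirichlet inner condition on u = r*rho"
        )
    return Basis(kind, bc_left, bc_right, float(domain_start), float(domain_end), int(N))


def collocation_points(basis: Basis) -> NDArray[np.float64]:
    """Midpoint collocation grid ``x_m = start + (m + 1/2) L / (N + 1)``.

    These are the ``N + 1`` interior points at which the reaction step acts
    and between which the fast transforms map; the forward/inverse transform
    pair on this grid is an exact identity (see :mod:`spectrakin.transform`).
    """
    m = np.arange(basis.N + 1, dtype=float)
    return basis.domain_start + (m + 0.5) * basis.L / (basis.N + 1)


def evaluate_basis(basis: Basis, n: int, position: ArrayLike) -> NDArray[np.float64] | float:
    """Evaluate ``phi_n`` at one or more positions inside the closed domain.

    For the radial family, ``phi_n(r) = sin(omega_n (r - a)) / r``; at
    ``r -> 0`` (only reachable when ``a = 0``) the analytic limit
    ``omega_n`` is returned for continuity.
    """
    if not 0 <= n <= basis.N:
        raise IndexError(f"mode index {n} outside 0..{basis.N}")
    x = np.asarray(position, dtype=float)
    w = basis.frequencies[n]
    if basis.kind is BasisKind.SINE:
        out = np.sin(w * (x - basis.domain_start))
    elif basis.kind is BasisKind.COSINE:
        out = np.cos(w * (x - basis.domain_start))
    else:
        arg = w * (x - basis.domain_start)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x == 0.0, w, np.sin(arg) / np.where(x == 0.0, 1.0, x))
    return out if out.ndim else float(out)


def synthesis_matrix(basis: Basis, points: ArrayLike | None = None) -> NDArray[np.float64]:
    """Vandermonde-style matrix ``Phi[m, n] = phi_n(points[m])``.

    Defaults to the collocation grid.  This is the O(N^2) reference path;
    the fast transforms must agree with it.
    """
    pts = collocation_points(basis) if points is None else np.asarray(points, float)
    return np.column_stack([evaluate_basis(basis, n, pts) for n in range(basis.N + 1)])


@dataclass
class SpectralField:
    """One species' concentration in dual representation.

    Holds the spectral coefficients ``c_n`` (amplitudes in the expansion,
    exactly — no hidden normalisation factors) and/or the concentration
    values on the collocation grid, with flags saying which representation
    is current.  The diffusion step acts on coefficients, the reaction step
    on values; :mod:`spectrakin.transform` keeps the two consistent.
    """

    basis: Basis
    coefficients: NDArray[np.float64] | None = None
    values: NDArray[np.float64] | None = None
    coefficients_current: bool = False
    values_current: bool = False

    def __post_init__(self) -> None:
        M = self.basis.n_modes
        if self.coefficients is None and self.values is None:
            self.coefficients = np.zeros(M)
            self.values = np.zeros(M)
            self.coefficients_current = True
            self.values_current = True
            return
        for name in ("coefficients", "values"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != (M,):
                    raise ValueError(f"{name} must have length N+1 = {M}, got {arr.shape}")
                setattr(self, name, arr)
        if self.coefficients is not None and not self.values_current:
            self.coefficients_current = True
        if self.values is not None and self.coefficients is None:
            self.values_current = True

    @classmethod
    def from_coefficients(cls, basis: Basis, c: ArrayLike) -> "SpectralField":
        return cls(basis, coefficients=np.asarray(c, float), coefficients_current=True)

    @classmethod
    def from_values(cls, basis: Basis, v: ArrayLike) -> "SpectralField":
        return cls(basis, values=np.asarray(v, float), values_current=True)

    def copy(self) -> "SpectralField":
        return SpectralField(
            self.basis,
            None if self.coefficients is None else self.coefficients.copy(),
            None if self.values is None else self.values.copy(),
            self.coefficients_current,
            self.values_current,
        )


def synthesize_naive(field: SpectralField, points: ArrayLike) -> NDArray[np.float64]:
    """Direct O(N^2) evaluation of the spectral sum at arbitrary points.

    Serves as the independent oracle for the fast transforms.
    """
    if not field.coefficients_current:
        raise ValueError("coefficients are not current; transform first")
    return synthesis_matrix(field.basis, points) @ field.coefficients
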