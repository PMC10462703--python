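"""Fast, exactly invertible maps between grid values and spectral coefficients.

On the midpoint collocation grid every supported basis family pairs with a
classical discrete trigonometric transform:

====================================  =======================================
family (frequencies)                  forward / inverse pair
====================================  =======================================
sine, Dirichlet-Neumann ((n+1/2)pi/L)   DST-IV (self-conjugate up to scale)
cosine, Neumann-Dirichlet               DCT-IV (self-conjugate up to scale)
sine, Dirichlet-Dirichlet (n' pi/L)     DST-II (forward) / DST-III (inverse)
cosine, Neumann-Neumann (n pi/L)        DCT-II (forward) / DCT-III (inverse)
====================================  =======================================

Normalisations are fixed so that the coefficients returned are the amplitudes
of the spectral expansion exactly.  The radial family transforms
``u = r * rho`` with the matching interval machinery on ``(r - a)`` and
divides by ``r`` on the way back.

Both directions also have an O(N^2) dense fallback built from the synthesis
matrix; the fast path is required (and tested) to agree with it to round-off.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import fft

from .basis import BC, Basis, BasisKind, SpectralField, collocation_points, synthesis_matrix

__all__ = [
    "to_coefficients",
    "to_values",
    "to_coefficients_dense",
    "to_values_dense",
    "ensure_coefficients",
    "ensure_values",
]


def _family(basis: Basis) -> tuple[str, bool]:
    """Return (trig, half_integer) of the interval machinery to use.

    trig is "sin" or "cos"; for the radial family the interval transform
    acts on u = r*rho so the sine rules apply.
    """
    if basis.kind is BasisKind.RADIAL_SINE:
        return "sin", basis.bc_right is BC.NEUMANN
    trig = "sin" if basis.kind is BasisKind.SINE else "cos"
    half = basis.bc_left != basis.bc_right
    return trig, half


def _interval_to_coefficients(v: NDArray, basis: Basis) -> NDArray:
    M = basis.n_modes
    trig, half = _family(basis)
    if half:
        t = fft.dst(v, type=4) if trig == "sin" else fft.dct(v, type=4)
        return t / M
    if trig == "cos":  # NN: DCT-II, mode 0 carries the full mean
        Y = fft.dct(v, type=2)
        c = Y / M
        c[0] = Y[0] / (2 * M)
        return c
    # DD sine (internal shift n' = n+1): DST-II; top mode alias has weight 2M
    Y = fft.dst(v, type=2)
    c = Y / M
    c[-1] = Y[-1] / (2 * M)
    return c


def _interval_to_values(c: NDArray, basis: Basis) -> NDArray:
    M = basis.n_modes
    trig, half = _family(basis)
    if half:
        return (fft.dst(c, type=4) if trig == "sin" else fft.dct(c, type=4)) / 2
    if trig == "cos":
        x = c.copy()
        x[1:] = c[1:] / 2
        return fft.dct(x, type=3)
    x = c / 2
    x[-1] = c[-1]
    return fft.dst(x, type=3)


def to_coefficients(values: ArrayLike, basis: Basis) -> NDArray[np.float64]:
    """Unique coefficients whose spectral sum interpolates the grid values.

    O(N log N) via the family's discrete transform.  For radial bases the
    input is the concentration rho on the grid; internally ``u = r * rho``
    is transformed.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != basis.n_modes:
        raise ValueError(f"expected length N+1 = {basis.n_modes}, got {v.shape[-1]}")
    if basis.kind is BasisKind.RADIAL_SINE:
        v = v * collocation_points(basis)
    return _interval_to_coefficients(v, basis)


def to_values(coefficients: ArrayLike, basis: Basis) -> NDArray[np.float64]:
    """Values of the spectral sum on the collocation grid (inverse transform)."""
    c = np.asarray(coefficients, dtype=float)
    if c.shape[-1] != basis.n_modes:
        raise ValueError(f"expected length N+1 = {basis.n_modes}, got {c.shape[-1]}")
    u = _interval_to_values(c, basis)
    if basis.kind is BasisKind.RADIAL_SINE:
        return u / collocation_points(basis)
    return u


def to_values_dense(coefficients: ArrayLike, basis: Basis) -> NDArray[np.float64]:
    """O(N^2) matrix fallback for :func:`to_values` (reference path)."""
    return synthesis_matrix(basis) @ np.asarray(coefficients, float)


def to_coefficients_dense(values: ArrayLike, basis: Basis) -> NDArray[np.float64]:
    """O(N^2) matrix-solve fallback for :func:`to_coefficients`."""
    return np.linalg.solve(synthesis_matrix(basis), np.asarray(values, float))


def ensure_coefficients(field: SpectralField) -> NDArray[np.float64]:
    """Make the coefficient representation current (transforming if needed)."""
    if not field.coefficients_current:
        field.coefficients = to_coefficients(field.values, field.basis)
        field.coefficients_current = True
    return field.coefficients


def ensure_values(field: SpectralField) -> NDArray[np.float64]:
    """Make the value representation current (transforming if needed)."""
    if not field.values_current:
        field.values = to_values(field.coefficients, field.basis)
        field.values_current = True
    return field.values
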