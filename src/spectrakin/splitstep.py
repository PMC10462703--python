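"""Strang split stepping: exact spectral diffusion + Kahan reaction.

One Strang step of length dt is

    diffusion(dt/2)  ->  reaction(dt) at every grid point  ->  diffusion(dt/2)

with the diffusion half-steps acting diagonally on the spectral coefficients,

.. math:: c_n(t + \\Delta t) = c_n(t) \\exp(-D \\omega_n^2 \\Delta t),

which is the exact flow of the diffusion semigroup in each basis — no
truncation error — at O(N) cost.  The splitting error is O(dt^3) per step
(globally second order), estimated by step doubling and kept below a
user tolerance by an adaptive halve/double controller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .basis import SpectralField
from .kinetics import KahanStepError, ReactionNetwork, kahan_step
from .transform import ensure_coefficients, ensure_values, to_coefficients

__all__ = [
    "SimulationState",
    "ToleranceSpec",
    "Trajectory",
    "TimeStepUnderflow",
    "diffusion_step",
    "strang_step",
    "adaptive_advance",
    "run",
]


class TimeStepUnderflow(RuntimeError):
    """The controller could not meet the tolerance at dt_min."""


@dataclass
class ToleranceSpec:
    """Adaptive-step control parameters.

    tol is the maximum absolute coefficient difference allowed between the
    one-step and two-half-step solutions of a macro step; if the estimate is
    below ``tol * grow_threshold`` the step size is doubled (capped at
    dt_max), if above tol the step is halved and redone (floored at dt_min).
    """

    tol: float = 1e-6
    dt_min: float = 1e-12
    dt_max: float = 10.0
    grow_threshold: float = 0.1  # err < tol * this => double dt
    negative_floor: float = 1e-9  # reject if min(rho) < -floor * max|rho|

    def __post_init__(self) -> None:
        if not (0 < self.dt_min <= self.dt_max):
            raise ValueError("need 0 < dt_min <= dt_max")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class EquilibriumSpec:
    """Effective-equilibrium detection: the concentrations stop changing.

    Declared when max over species and grid points of
    ``|drho| / (dt_macro * (|rho| + floor))`` stays below rate_tol (ns^-1)
    for ``consecutive`` accepted macro steps.
    """

    rate_tol: float = 1e-6
    floor: float = 1e-12
    consecutive: int = 3


@dataclass
class SimulationState:
    """All species' spectral fields plus the running clock and controller."""

    fields: dict[str, SpectralField]
    time: float = 0.0
    dt: float = 1e-3
    step_count: int = 0
    accepted: int = 0
    rejected: int = 0

    def __post_init__(self) -> None:
        sizes = {f.basis.n_modes for f in self.fields.values()}
        if len(sizes) > 1:
            raise ValueError("all species fields must share the same N")

    def copy(self) -> "SimulationState":
        return SimulationState(
            {k: f.copy() for k, f in self.fields.items()},
            self.time, self.dt, self.step_count, self.accepted, self.rejected,
        )

    def coefficient_block(self) -> NDArray[np.float64]:
        return np.stack([ensure_coefficients(f) for f in self.fields.values()])

    def value_block(self) -> NDArray[np.float64]:
        return np.stack([ensure_values(f) for f in self.fields.values()])


def diffusion_step(field: SpectralField, D: float, dt: float) -> SpectralField:
    """Exact diffusion propagation: ``c_n *= exp(-D omega_n^2 dt)`` in place.

    For radial fields the coefficients already describe ``u = r * rho``, on
    which the radial Laplacian is the plain 1D second derivative, so the same
    diagonal decay applies verbatim.
    """
    if D < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    c = ensure_coefficients(field)
    if D > 0 and dt != 0.0:
        c *= np.exp(-D * field.basis.frequencies**2 * dt)
    field.values_current = False
    return field


def strang_step(state: SimulationState, network: ReactionNetwork, dt: float) -> SimulationState:
    """One Strang macro-update of length dt, in place.

    diffusion(dt/2) on coefficients -> inverse transform -> Kahan(dt) at each
    collocation point (the point problems are independent) -> forward
    transform -> diffusion(dt/2).
    """
    names = network.names()
    D = network.diffusion_coefficients
    for name, Ds in zip(names, D):
        diffusion_step(state.fields[name], Ds, dt / 2.0)
    rho = np.stack([ensure_values(state.fields[n]) for n in names], axis=-1)  # (P, S)
    rho = kahan_step(network, rho, dt)
    for j, name in enumerate(names):
        f = state.fields[name]
        f.values = np.ascontiguousarray(rho[:, j])
        f.values_current = True
        f.coefficients = to_coefficients(f.values, f.basis)
        f.coefficients_current = True
        diffusion_step(f, D[j], dt / 2.0)
    state.time += dt
    state.step_count += 1
    return state


def _try_double_step(
    state: SimulationState, network: ReactionNetwork, dt: float
) -> tuple[SimulationState, SimulationState]:
    """Candidate (one dt step) and reference (two dt/2 steps) from state."""
    coarse = state.copy()
    strang_step(coarse, network, dt)
    fine = state.copy()
    strang_step(fine, network, dt / 2.0)
    strang_step(fine, network, dt / 2.0)
    return coarse, fine


def adaptive_advance(
    state: SimulationState,
    network: ReactionNetwork,
    tolerances: ToleranceSpec,
) -> tuple[SimulationState, float]:
    """One accepted macro step; returns (new state, error estimate).

    The error estimate is the maximum absolute coefficient difference, over
    all species and modes, between one dt step and two dt/2 steps; the
    accepted state is the finer (two half-step) result.  On rejection dt is
    halved and the step recomputed; a step that still fails at dt_min raises
    :class:`TimeStepUnderflow`.
    """
    dt = state.dt
    start_min = float(state.value_block().min())
    while True:
        try:
            coarse, fine = _try_double_step(state, network, dt)
            err = float(
                max(
                    np.max(np.abs(ensure_coefficients(coarse.fields[n])
                                  - ensure_coefficients(fine.fields[n])))
                    for n in fine.fields
                )
            )
            # reject steps that *produce* significant negatives (undershoot of
            # the Kahan step); data that starts signed is left alone
            vals = fine.value_block()
            bad_negative = vals.min() < min(start_min, 0.0) - (
                tolerances.negative_floor * max(np.abs(vals).max(), 1e-300)
            )
            ok = err <= tolerances.tol and not bad_negative
        except KahanStepError:
            ok, err = False, math.inf
        if ok:
            break
        if dt <= tolerances.dt_min * (1 + 1e-12):
            raise TimeStepUnderflow(
                f"error estimate {err:g} exceeds tol {tolerances.tol:g} "
                f"at dt_min={tolerances.dt_min:g} (t={state.time:g} ns)"
            )
        dt = max(dt / 2.0, tolerances.dt_min)
        state.rejected += 1
    fine.accepted = state.accepted + 1
    fine.rejected = state.rejected
    fine.dt = dt
    if err < tolerances.tol * tolerances.grow_threshold:
        fine.dt = min(2.0 * dt, tolerances.dt_max)
    return fine, err


@dataclass
class Trajectory:
    """Sampled output of :func:`run`: times, observables and controller log."""

    times: list[float] = field(default_factory=list)
    observables: dict[str, list[float]] = field(default_factory=dict)
    error_trace: list[float] = field(default_factory=list)
    dt_trace: list[float] = field(default_factory=list)
    snapshots: list[tuple[float, dict[str, NDArray]]] = field(default_factory=list)
    reached_equilibrium: bool = False
    final_state: SimulationState | None = None
    accepted: int = 0
    rejected: int = 0

    def observable(self, name: str) -> NDArray[np.float64]:
        return np.asarray(self.observables[name], float)

    @property
    def time_array(self) -> NDArray[np.float64]:
        return np.asarray(self.times, float)


def run(
    state: SimulationState,
    network: ReactionNetwork,
    tolerances: ToleranceSpec | None = None,
    *,
    t_end: float | None = None,
    equilibrium: EquilibriumSpec | None = None,
    observables: dict | None = None,
    snapshot_times: list[float] | None = None,
    max_steps: int = 500_000,
) -> Trajectory:
    """Advance until t_end and/or effective equilibrium, recording output.

    Parameters
    ----------
    observables
        Mapping name -> callable(state) evaluated after every accepted macro
        step (and at t=0).
    equilibrium
        If given, stop early once the relative rate of change stays below
        ``rate_tol`` for ``consecutive`` accepted steps.  At least one of
        t_end / equilibrium must be provided.
    snapshot_times
        Times at which full per-species value profiles are stored (the
        closest accepted step at or after each requested time).
    """
    if t_end is None and equilibrium is None:
        raise ValueError("provide t_end and/or an equilibrium criterion")
    tolerances = tolerances or ToleranceSpec()
    observables = observables or {}
    pending_snapshots = sorted(snapshot_times or [])
    traj = Trajectory(observables={k: [] for k in observables})

    def record(st: SimulationState, err: float | None) -> None:
        traj.times.append(st.time)
        for k, fn in observables.items():
            traj.observables[k].append(float(fn(st)))
        if err is not None:
            traj.error_trace.append(err)
            traj.dt_trace.append(st.dt)

    record(state, None)
    if pending_snapshots and pending_snapshots[0] <= state.time:
        traj.snapshots.append((state.time, {k: v.copy() for k, v in
                                            zip(state.fields, state.value_block())}))
        pending_snapshots = [t for t in pending_snapshots if t > state.time]

    calm_streak = 0
    prev_vals = state.value_block()
    for _ in range(max_steps):
        if t_end is not None:
            if state.time >= t_end * (1 - 1e-12):
                break
            state.dt = min(state.dt, t_end - state.time)
        t_before = state.time
        state, err = adaptive_advance(state, network, tolerances)
        record(state, err)
        vals = state.value_block()
        while pending_snapshots and state.time >= pending_snapshots[0]:
            traj.snapshots.append(
                (state.time, dict(zip(state.fields, (v.copy() for v in vals))))
            )
            pending_snapshots.pop(0)
        if equilibrium is not None:
            dt_macro = state.time - t_before
            rate = np.abs(vals - prev_vals) / (dt_macro * (np.abs(vals) + equilibrium.floor))
            calm_streak = calm_streak + 1 if rate.max() < equilibrium.rate_tol else 0
            if calm_streak >= equilibrium.consecutive:
                traj.reached_equilibrium = True
                break
        prev_vals = vals
    else:
        warnings.warn(
            f"run() hit max_steps={max_steps} before the stop criterion "
            f"(t={state.time:g} ns); returning partial trajectory",
            RuntimeWarning,
            stacklevel=2,
        )
    traj.final_state = state
    traj.accepted = state.accepted
    traj.rejected = state.rejected
    return traj
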