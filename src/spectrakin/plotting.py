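"""Optional matplotlib helpers (import is deferred so the solver has no hard
plotting dependency)."""

from __future__ import annotations

import numpy as np

from .basis import synthesize_naive
from .splitstep import SimulationState, Trajectory
from .transform import ensure_coefficients

__all__ = ["plot_profiles", "plot_scan", "plot_hollowing"]


def _pyplot():
    import matplotlib.pyplot as plt

    return plt


def plot_profiles(state: SimulationState, species=None, n_points: int = 400, ax=None):
    """Concentration profiles of the given species (default: all)."""
    plt = _pyplot()
    ax = ax or plt.gca()
    names = species or list(state.fields)
    for name in names:
        f = state.fields[name]
        ensure_coefficients(f)
        a, b = f.basis.domain_start, f.basis.domain_end
        x = np.linspace(a, b, n_points + 1)
        if f.basis.is_radial and a == 0:
            x = x[1:]
        ax.plot(x, synthesize_naive(f, x), label=name)
    ax.set_xlabel("position (nm)")
    ax.set_ylabel("concentration")
    ax.legend()
    return ax


def plot_scan(table, ax=None):
    """Equilibrium boundary concentration vs thickness, one line per dose rate."""
    plt = _pyplot()
    ax = ax or plt.gca()
    for dose, grp in table.groupby("dose_rate"):
        ax.loglog(grp.L_nm, grp.boundary_eq, "x-", label=f"{dose:g} Gy/ns")
    ax.set_xlabel("water layer thickness L (nm)")
    ax.set_ylabel("boundary concentration at equilibrium")
    ax.legend()
    return ax


def plot_hollowing(trajectory: Trajectory, species: str, ax=None):
    """Centre/max ratio of a radial profile over time."""
    from .radiolysis import hollowing_metrics

    plt = _pyplot()
    ax = ax or plt.gca()
    onset, ratio = hollowing_metrics(trajectory, species)
    ax.plot(trajectory.time_array, ratio, label=f"{species} centre/max")
    if onset is not None:
        ax.axvline(onset, ls="--", color="k", label=f"onset {onset:g} ns")
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("centre / max")
    ax.legend()
    return ax
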