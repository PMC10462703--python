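"""Radiolysis scenarios: thin water films over an absorbing interface, and
spherically symmetric radiolytic spurs.

Film geometry
    A 1D column perpendicular to a solid (e.g. plutonium-oxide) surface that
    acts as a perfect sink (Dirichlet at x = 0), with a zero-net-flux
    water-gas boundary at x = L (Neumann), hence the Dirichlet-Neumann sine
    basis.  Continuous irradiation enters as zeroth-order source reactions
    whose rate constants come from radiation-chemical yields (G-values,
    species per 100 eV) and the dose rate (Gy ns^-1).  1D concentrations are
    Species nm^-1 for an assumed column cross-section (default 1 nm^2).

Spur geometry
    An isolated cluster of radiolysis products around an ionisation event,
    modelled as spherically symmetric Gaussian initial distributions
    ``rho(r) = N0 (2 pi sigma^2)^{-3/2} exp(-r^2 / 2 sigma^2)`` on a radial
    sine basis (regularity at r = 0, Dirichlet at an outer radius b far
    beyond the spur).  Concentrations are Species nm^-3.  When the solvated
    electron's distribution is wider than the hydroxyl radical's, fast
    recombination near the origin hollows out the electron profile — the
    central minimum this module measures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .basis import BC, Basis, BasisKind, SpectralField, collocation_points, make_basis
from .kinetics import Reaction, ReactionNetwork
from .splitstep import EquilibriumSpec, SimulationState, ToleranceSpec, Trajectory, run
from .transform import ensure_coefficients, ensure_values, to_coefficients

__all__ = [
    "ScenarioConfig",
    "gvalue_to_source",
    "build_film_scenario",
    "build_spur_scenario",
    "boundary_concentration",
    "inventory",
    "center_value",
    "scan_film",
    "hollowing_metrics",
    "MONOLAYER_NM",
]

#: One adsorbed monolayer of water is approximately 0.25 nm thick.
MONOLAYER_NM = 0.25
_EV = 1.602176634e-19  # J per eV
_WATER_DENSITY = 997.0  # kg m^-3 at room temperature


@dataclass
class ScenarioConfig:
    """Geometry, irradiation and run controls for one scenario.

    Film scenarios give ``thickness_nm`` (or ``monolayers``), ``dose_rate``
    and ``g_values``; spur scenarios give ``initial_gaussians`` mapping each
    species to a profile spec and optionally the outer radius ``b_nm``
    (default 40x the widest initial sigma).  A Gaussian spec is
    ``{"sigma": nm, "N0": count}``; a hollowed (ballistic-transit) profile is
    ``{"sigma": nm, "N0": count, "hollow_sigma": nm, "hollow_depth": 0..1}``,
    a Gaussian minus a narrower Gaussian renormalised to N0.
    """

    geometry: str = "film"  # "film" | "spur"
    thickness_nm: float | None = None
    monolayers: float | None = None
    bc_left: str = "dirichlet"
    bc_right: str = "neumann"
    dose_rate: float = 0.0  # Gy ns^-1
    g_values: dict[str, float] = dc_field(default_factory=dict)  # per 100 eV
    cross_section_nm2: float = 1.0
    density_kg_m3: float = _WATER_DENSITY
    spur_energy_eV: float = 100.0
    b_nm: float | None = None
    initial_gaussians: dict[str, dict] = dc_field(default_factory=dict)
    N: int = 100
    dt0: float = 1e-3  # ns
    tol: float = 1e-6
    dt_min: float = 1e-12
    dt_max: float = 10.0
    t_end: float | None = None
    max_steps: int = 500_000

    @property
    def L(self) -> float:
        if self.thickness_nm is not None:
            return float(self.thickness_nm)
        if self.monolayers is not None:
            return MONOLAYER_NM * float(self.monolayers)
        raise ValueError("film scenario needs thickness_nm or monolayers")

    def tolerance_spec(self) -> ToleranceSpec:
        return ToleranceSpec(tol=self.tol, dt_min=self.dt_min, dt_max=self.dt_max)


def gvalue_to_source(
    g_value: float,
    dose_rate: float,
    geometry: str = "film",
    *,
    cross_section_nm2: float = 1.0,
    density_kg_m3: float = _WATER_DENSITY,
) -> float:
    """Convert a G-value and dose rate to a zeroth-order source constant.

    ``S = (G / 100) * dose_rate * m / q_eV`` where m is the water mass per
    unit length of the 1D column (film; density x cross-section, giving
    Species nm^-1 ns^-1) or per unit volume (spur; Species nm^-3 ns^-1), and
    q_eV converts joules to eV.  Linear in both G and the dose rate.
    """
    if g_value < 0 or dose_rate < 0:
        raise ValueError("g_value and dose_rate must be >= 0")
    if geometry == "film":
        mass = density_kg_m3 * cross_section_nm2 * 1e-27  # kg per nm of column
    elif geometry == "spur":
        mass = density_kg_m3 * 1e-27  # kg per nm^3
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    ev_rate = dose_rate * mass / _EV  # eV per nm (or nm^3) per ns
    return (g_value / 100.0) * ev_rate


def _source_reactions(config: ScenarioConfig, network: ReactionNetwork) -> list[Reaction]:
    missing = [s for s in config.g_values if s not in network.index]
    if missing:
        raise KeyError(
            f"G-value table references species not in the network: {missing}"
        )
    out = []
    for name, g in config.g_values.items():
        S = gvalue_to_source(
            g,
            config.dose_rate,
            "film",
            cross_section_nm2=config.cross_section_nm2,
            density_kg_m3=config.density_kg_m3,
        )
        out.append(Reaction((), (name,), S, label=f"source:{name}"))
    return out


def build_film_scenario(
    config: ScenarioConfig, network: ReactionNetwork
) -> tuple[SimulationState, ReactionNetwork]:
    """Thin-film setup: DN sine basis on [0, L], zero initial concentrations,
    per-species zeroth-order sources from the G-value table.

    The network's second-order constants are assumed volumetric (nm^3 ns^-1)
    and are rescaled to the 1D column system (nm ns^-1) by the cross-section.
    """
    L = config.L
    if L <= 0:
        raise ValueError("film thickness must be positive")
    kind = BasisKind.SINE if config.bc_left == "dirichlet" else BasisKind.COSINE
    basis = make_basis(kind, config.bc_left, config.bc_right, 0.0, L, config.N)
    net1d = network.scaled_second_order(1.0 / config.cross_section_nm2)
    net1d = net1d.with_reactions(_source_reactions(config, net1d))
    fields = {s.name: SpectralField(basis) for s in net1d.species}
    state = SimulationState(fields, dt=config.dt0)
    return state, net1d


def _gaussian_profile(r: NDArray, spec: dict) -> NDArray:
    """3D Gaussian (optionally hollowed) radial profile normalised to N0."""
    sigma = float(spec["sigma"])
    N0 = float(spec.get("N0", 0.0))
    main = np.exp(-(r**2) / (2 * sigma**2))
    mass = (2 * np.pi * sigma**2) ** 1.5
    if "hollow_sigma" in spec:
        si = float(spec["hollow_sigma"])
        depth = float(spec.get("hollow_depth", 1.0))
        if not si < sigma:
            raise ValueError("hollow_sigma must be narrower than sigma")
        main = main - depth * np.exp(-(r**2) / (2 * si**2))
        mass = mass - depth * (2 * np.pi * si**2) ** 1.5
        if mass <= 0:
            raise ValueError("hollowed profile has non-positive total mass")
    return N0 * main / mass


def _gaussian_tail_fraction(b: float, sigma: float) -> float:
    """Mass fraction of a 3D Gaussian beyond radius b (Maxwell tail)."""
    z = b / sigma
    return math.erfc(z / math.sqrt(2)) + math.sqrt(2 / math.pi) * z * math.exp(-z * z / 2)


def build_spur_scenario(
    config: ScenarioConfig, network: ReactionNetwork
) -> tuple[SimulationState, ReactionNetwork]:
    """Radial spur setup from per-species Gaussian initial distributions.

    Raises if the outer radius truncates any initial profile by more than
    1e-6 of its mass (suggesting a larger b).
    """
    specs = config.initial_gaussians
    sigmas = [float(v["sigma"]) for v in specs.values() if v.get("N0", 0)]
    if not sigmas:
        sigmas = [1.0]
    b = config.b_nm if config.b_nm is not None else 40.0 * max(sigmas)
    for name, spec in specs.items():
        if name not in network.index:
            raise KeyError(f"initial profile for unknown species {name!r}")
        if spec.get("N0", 0) and _gaussian_tail_fraction(b, float(spec["sigma"])) > 1e-6:
            raise ValueError(
                f"outer radius b={b} nm truncates the initial profile of {name} "
                f"(sigma={spec['sigma']} nm) by more than 1e-6 of its mass; "
                "increase b_nm"
            )
    basis = make_basis(BasisKind.RADIAL_SINE, BC.DIRICHLET, BC.DIRICHLET, 0.0, b, config.N)
    r = collocation_points(basis)
    fields = {}
    for s in network.species:
        spec = specs.get(s.name)
        if spec is None or not spec.get("N0", 0):
            fields[s.name] = SpectralField(basis)
        else:
            fields[s.name] = SpectralField.from_values(basis, _gaussian_profile(r, spec))
            ensure_coefficients(fields[s.name])
    state = SimulationState(fields, dt=config.dt0)
    return state, network


def _mode_integrals(basis: Basis) -> NDArray[np.float64]:
    """Closed-form integral of each basis function over the domain.

    Interval bases: plain dx integrals.  Radial bases: integrals against the
    volume element, i.e. ``4 pi \\int phi_n r^2 dr`` so that
    ``inventory = integrals @ c`` is the particle count.
    """
    w = basis.frequencies
    L = basis.L
    a = basis.domain_start
    if basis.kind is BasisKind.SINE:
        return (1.0 - np.cos(w * L)) / w
    if basis.kind is BasisKind.COSINE:
        out = np.empty_like(w)
        nz = w > 0
        out[nz] = np.sin(w[nz] * L) / w[nz]
        out[~nz] = L
        return out
    # radial: 4 pi int_a^b (s + a) sin(w s) ds with s = r - a
    sL, cL = np.sin(w * L), np.cos(w * L)
    return 4 * np.pi * ((sL - w * L * cL) / w**2 + a * (1.0 - cL) / w)


def inventory(state: SimulationState, species: str) -> float:
    """Total particle count of a species: ``int rho dx`` (film) or
    ``4 pi int rho r^2 dr`` (spur), from closed-form mode integrals."""
    f = state.fields[species]
    return float(_mode_integrals(f.basis) @ ensure_coefficients(f))


def boundary_concentration(state: SimulationState, species: str, end: str = "right") -> float:
    """Concentration at a domain endpoint by direct spectral summation.

    A Dirichlet end returns exactly 0.  For the DN sine family at the right
    (Neumann) end this is ``sum_n c_n (-1)^n``.
    """
    f = state.fields[species]
    basis = f.basis
    bc = basis.bc_right if end == "right" else basis.bc_left
    if bc is BC.DIRICHLET:
        return 0.0
    x = basis.domain_end if end == "right" else basis.domain_start
    c = ensure_coefficients(f)
    if basis.kind is BasisKind.SINE:
        phi = np.sin(basis.frequencies * (x - basis.domain_start))
    else:
        phi = np.cos(basis.frequencies * (x - basis.domain_start))
    return float(phi @ c)


def center_value(state: SimulationState, species: str) -> float:
    """rho at the origin of a radial field (analytic r->0 limit sum c_n w_n)."""
    f = state.fields[species]
    if f.basis.kind is not BasisKind.RADIAL_SINE or f.basis.domain_start != 0:
        raise ValueError("center_value requires a radial basis with a = 0")
    return float(f.basis.frequencies @ ensure_coefficients(f))


def run_film(
    config: ScenarioConfig,
    network: ReactionNetwork,
    *,
    track_species: str = "H2",
    equilibrium: EquilibriumSpec | None = None,
) -> Trajectory:
    """Run one film scenario to t_end and/or effective equilibrium, tracking
    the boundary concentration and inventory of one species."""
    state, net = build_film_scenario(config, network)
    obs = {
        f"boundary:{track_species}": lambda st: boundary_concentration(st, track_species),
        f"inventory:{track_species}": lambda st: inventory(st, track_species),
    }
    if equilibrium is None and config.t_end is None:
        equilibrium = EquilibriumSpec()
    return run(
        state, net, config.tolerance_spec(),
        t_end=config.t_end, equilibrium=equilibrium,
        observables=obs, max_steps=config.max_steps,
    )


def run_spur(
    config: ScenarioConfig,
    network: ReactionNetwork,
    *,
    track_species: tuple[str, ...] = ("e_aq",),
    snapshot_times: list[float] | None = None,
) -> Trajectory:
    """Run one spur scenario to t_end, tracking per-species centre value,
    profile maximum and inventory for the hollowing diagnostics."""
    if config.t_end is None:
        raise ValueError("spur runs need t_end")
    state, net = build_spur_scenario(config, network)
    obs = {}
    for sp in track_species:
        obs[f"center:{sp}"] = (lambda st, s=sp: center_value(st, s))
        obs[f"max:{sp}"] = (lambda st, s=sp: float(ensure_values(st.fields[s]).max()))
        obs[f"inventory:{sp}"] = (lambda st, s=sp: inventory(st, s))
    return run(
        state, net, config.tolerance_spec(),
        t_end=config.t_end, observables=obs,
        snapshot_times=snapshot_times, max_steps=config.max_steps,
    )


def hollowing_metrics(
    trajectory: Trajectory, species: str, *, delta: float = 0.01
) -> tuple[float | None, NDArray[np.float64]]:
    """Onset time of a central minimum and the centre/max ratio series.

    The onset is the first sampled time at which the profile value at the
    origin falls below the profile maximum by more than the relative margin
    delta.  Returns (onset or None, ratio time series).
    """
    center = trajectory.observable(f"center:{species}")
    peak = trajectory.observable(f"max:{species}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(peak > 0, center / peak, 1.0)
    hollow = center < (1.0 - delta) * peak
    idx = np.flatnonzero(hollow)
    onset = float(trajectory.time_array[idx[0]]) if idx.size else None
    return onset, ratio


def _build(config: ScenarioConfig, network: ReactionNetwork):
    if config.geometry == "film":
        return build_film_scenario(config, network)
    if config.geometry == "spur":
        return build_spur_scenario(config, network)
    raise ValueError(f"unknown geometry {config.geometry!r}")


def convergence_report(
    config: ScenarioConfig,
    network: ReactionNetwork,
    *,
    n_query: int = 201,
) -> dict[str, float]:
    """Self-verification protocol: rerun with dt0/2 and 2N, compare profiles.

    Both runs use a fixed macro step (the adaptive controller is pinned by
    setting dt_max = dt0 and an unbounded tolerance), advance to the same
    stop criterion, and the final per-species profiles are compared on a
    shared uniform query grid.  Reports both the maximum absolute difference
    (concentration units) and the maximum relative difference
    (dimensionless, normalised per species by its refined profile maximum).
    """
    import dataclasses as _dc

    from .basis import synthesize_naive

    results = []
    for factor in (1, 2):
        cfg = _dc.replace(config, N=config.N * factor, dt0=config.dt0 / factor)
        state, net = _build(cfg, network)
        state.dt = cfg.dt0
        tspec = ToleranceSpec(tol=np.inf, dt_min=cfg.dt_min, dt_max=cfg.dt0)
        eq = None if cfg.t_end is not None else EquilibriumSpec()
        traj = run(state, net, tspec, t_end=cfg.t_end, equilibrium=eq,
                   max_steps=cfg.max_steps)
        results.append(traj.final_state)
    coarse, fine = results
    some_basis = next(iter(fine.fields.values())).basis
    x = np.linspace(some_basis.domain_start, some_basis.domain_end, n_query)
    if some_basis.is_radial:
        x = x[1:]  # avoid the coordinate singularity at r = 0
    max_abs = 0.0
    max_rel = 0.0
    for name in fine.fields:
        ensure_coefficients(coarse.fields[name])
        ensure_coefficients(fine.fields[name])
        pc = synthesize_naive(coarse.fields[name], x)
        pf = synthesize_naive(fine.fields[name], x)
        diff = float(np.max(np.abs(pc - pf)))
        scale = float(np.max(np.abs(pf)))
        max_abs = max(max_abs, diff)
        if scale > 0:
            max_rel = max(max_rel, diff / scale)
    return {"max_abs_difference": max_abs, "max_rel_difference": max_rel}


def scan_film(
    network: ReactionNetwork,
    g_values: dict[str, float],
    thicknesses_nm: list[float],
    dose_rates: list[float],
    *,
    track_species: str = "H2",
    N: int = 64,
    tol: float | str = "auto",
    t_max: float = 1000.0,
    tol_rel: float = 1e-4,
    fit_window_nm: tuple[float, float] = (0.25, 5.0),
    **config_kwargs,
) -> tuple[pd.DataFrame, dict[float, float]]:
    """Equilibrium boundary concentration across a thickness x dose-rate grid,
    plus the fitted log-log slope per dose rate over the stated window.

    Returns (table, slopes) where the table has one row per run with columns
    ``L_nm, dose_rate, boundary_eq, equilibrated, in_fit_window`` and slopes
    maps each dose rate to the least-squares slope of
    ``log(boundary) vs log(L)`` over equilibrated runs inside the window.

    The step-control tolerance is an *absolute* coefficient tolerance, so by
    default (``tol="auto"``) it is scaled per run to the expected field
    magnitude: ``tol = tol_rel * max_s(S_s L^2 / 2 D_s)``, the
    diffusion-limited equilibrium scale of the sourced species.  A fixed
    absolute tol across dose rates spanning many orders of magnitude would
    be either blind (tol far above the coefficients) or unreachable.
    """
    lo, hi = fit_window_nm
    in_window = [lo <= L <= hi for L in thicknesses_nm]
    if sum(in_window) < 3:
        raise ValueError("need >= 3 thicknesses inside the fit window")
    rows = []
    for dose in dose_rates:
        for L, inw in zip(thicknesses_nm, in_window):
            if tol == "auto":
                scale = max(
                    (gvalue_to_source(g, dose) * L**2
                     / (2 * network.diffusion_coefficients[network.index[s]])
                     for s, g in g_values.items()
                     if network.diffusion_coefficients[network.index[s]] > 0),
                    default=0.0,
                )
                run_tol = tol_rel * scale if scale > 0 else 1e-6
            else:
                run_tol = float(tol)
            cfg = ScenarioConfig(
                geometry="film", thickness_nm=L, dose_rate=dose,
                g_values=g_values, N=N, tol=run_tol, t_end=t_max, **config_kwargs,
            )
            traj = run_film(cfg, network, track_species=track_species,
                            equilibrium=EquilibriumSpec())
            rows.append({
                "L_nm": L,
                "dose_rate": dose,
                "boundary_eq": traj.observable(f"boundary:{track_species}")[-1],
                "equilibrated": traj.reached_equilibrium,
                "in_fit_window": inw,
            })
    table = pd.DataFrame(rows)
    slopes: dict[float, float] = {}
    for dose, grp in table.groupby("dose_rate"):
        fit = grp[grp.in_fit_window]
        bad = fit[~fit.equilibrated]
        if len(bad):
            warnings.warn(
                f"excluding {len(bad)} non-equilibrated runs from the slope fit "
                f"at dose rate {dose:g} Gy/ns", RuntimeWarning, stacklevel=2,
            )
            fit = fit[fit.equilibrated]
        if len(fit) >= 3 and (fit.boundary_eq > 0).all():
            slopes[dose] = float(
                np.polyfit(np.log(fit.L_nm), np.log(fit.boundary_eq), 1)[0]
            )
        else:
            slopes[dose] = float("nan")
    return table, slopes
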