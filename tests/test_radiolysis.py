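"""Scenario layer: dose-to-source conversion, film and spur builders,
observables, the thickness scan and the hollowing diagnostics."""

import numpy as np
import pytest

from spectrakin import (
    Reaction,
    ReactionNetwork,
    ScenarioConfig,
    Species,
    boundary_concentration,
    build_film_scenario,
    build_spur_scenario,
    center_value,
    collocation_points,
    convergence_report,
    gvalue_to_source,
    hollowing_metrics,
    inventory,
    make_basis,
    run_spur,
    scan_film,
    synthesize_naive,
)
from spectrakin.basis import SpectralField
from spectrakin.fixtures import zero_network
from spectrakin.oracle import quadrature
from spectrakin.radiolysis import MONOLAYER_NM, run_film
from spectrakin.splitstep import EquilibriumSpec, SimulationState
from spectrakin.transform import ensure_coefficients


class TestGvalueToSource:
    def test_zero_yield_zero_source(self):
        assert gvalue_to_source(0.0, 1e-2) == 0.0

    def test_linear_in_dose_rate_and_g(self):
        s1 = gvalue_to_source(1.0, 1e-2)
        assert gvalue_to_source(1.0, 2e-2) == pytest.approx(2 * s1, rel=1e-14)
        assert gvalue_to_source(3.0, 1e-2) == pytest.approx(3 * s1, rel=1e-14)

    def test_dimensional_bookkeeping(self):
        """G = 100 per 100 eV with unit energy deposition rate gives S = 1."""
        # choose dose rate so that density*A*dose/q_eV = 1 eV / nm / ns
        q = 1.602176634e-19
        m_lin = 997.0 * 1e-27  # kg per nm at 1 nm^2 cross-section
        dose = q / m_lin
        assert gvalue_to_source(100.0, dose) == pytest.approx(1.0, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            gvalue_to_source(-1.0, 1.0)


class TestFilmBuilder:
    def test_dn_basis_and_frequencies(self, water_network, alpha_gvalues):
        cfg = ScenarioConfig(thickness_nm=0.5, N=100, dose_rate=1e-2,
                             g_values=alpha_gvalues)
        state, net = build_film_scenario(cfg, water_network)
        basis = state.fields["H2"].basis
        assert basis.n_modes == 101
        assert basis.frequencies[0] == pytest.approx(np.pi / 1.0)  # (pi/0.5)/2

    def test_monolayer_conversion(self, water_network, alpha_gvalues):
        cfg = ScenarioConfig(monolayers=2, N=10, g_values=alpha_gvalues)
        state, _ = build_film_scenario(cfg, water_network)
        assert state.fields["H2"].basis.domain_end == pytest.approx(2 * MONOLAYER_NM)

    def test_sources_installed_per_gvalue(self, water_network, alpha_gvalues):
        cfg = ScenarioConfig(thickness_nm=1.0, N=10, dose_rate=1e-2,
                             g_values=alpha_gvalues)
        _, net = build_film_scenario(cfg, water_network)
        sources = [r for r in net.reactions if r.order == 0]
        assert len(sources) == len(alpha_gvalues)
        by_product = {r.products[0]: r.rate_constant for r in sources}
        assert by_product["H2"] == pytest.approx(
            gvalue_to_source(alpha_gvalues["H2"], 1e-2)
        )

    def test_unknown_gvalue_species_rejected(self, water_network):
        cfg = ScenarioConfig(thickness_nm=1.0, N=10, dose_rate=1.0,
                             g_values={"Xe": 1.0})
        with pytest.raises(KeyError, match="Xe"):
            build_film_scenario(cfg, water_network)

    def test_zero_dose_rate_stays_identically_zero(self, water_network, alpha_gvalues):
        cfg = ScenarioConfig(thickness_nm=0.5, N=16, dose_rate=0.0,
                             g_values=alpha_gvalues, t_end=0.1)
        traj = run_film(cfg, water_network)
        assert traj.observable("boundary:H2")[-1] == 0.0
        assert traj.observable("inventory:H2")[-1] == 0.0


class TestSpurBuilder:
    def test_initial_inventory_matches_n0(self, water_network):
        cfg = ScenarioConfig(
            geometry="spur", b_nm=20.0, N=160,
            initial_gaussians={"e_aq": {"sigma": 2.3, "N0": 4.78}},
        )
        state, _ = build_spur_scenario(cfg, water_network)
        assert inventory(state, "e_aq") == pytest.approx(4.78, rel=1e-4)
        # quadrature oracle on the synthesized profile agrees
        f = state.fields["e_aq"]
        val = 4 * np.pi * quadrature(
            lambda r: synthesize_naive(f, r), (1e-6, 20.0), lambda r: r**2
        )
        assert val == pytest.approx(4.78, rel=1e-4)

    def test_truncation_guard_triggers(self, water_network):
        cfg = ScenarioConfig(
            geometry="spur", b_nm=5.0, N=40,
            initial_gaussians={"e_aq": {"sigma": 2.3, "N0": 4.78}},
        )
        with pytest.raises(ValueError, match="b_nm"):
            build_spur_scenario(cfg, water_network)

    def test_default_outer_radius_is_40_sigma(self, water_network):
        cfg = ScenarioConfig(
            geometry="spur", N=40,
            initial_gaussians={"e_aq": {"sigma": 1.5, "N0": 1.0},
                               "OH": {"sigma": 0.5, "N0": 1.0}},
        )
        state, _ = build_spur_scenario(cfg, water_network)
        assert state.fields["e_aq"].basis.domain_end == pytest.approx(60.0)

    def test_absent_species_zero_field(self, water_network):
        cfg = ScenarioConfig(
            geometry="spur", b_nm=20.0, N=40,
            initial_gaussians={"e_aq": {"sigma": 2.3, "N0": 4.78}},
        )
        state, _ = build_spur_scenario(cfg, water_network)
        assert inventory(state, "H2O2") == 0.0

    def test_hollow_initial_profile_mass_and_dip(self, water_network):
        cfg = ScenarioConfig(
            geometry="spur", b_nm=20.0, N=160,
            initial_gaussians={"e_aq": {"sigma": 2.3, "N0": 4.78,
                                        "hollow_sigma": 1.0, "hollow_depth": 0.6}},
        )
        state, _ = build_spur_scenario(cfg, water_network)
        assert inventory(state, "e_aq") == pytest.approx(4.78, rel=1e-4)
        assert center_value(state, "e_aq") < 0.99 * max(
            state.fields["e_aq"].values
        )


class TestObservables:
    def test_dirichlet_end_is_exactly_zero(self, rng):
        b = make_basis("sine", "dirichlet", "neumann", 0, 1, 9)
        st = SimulationState({"A": SpectralField.from_coefficients(
            b, rng.standard_normal(10))})
        assert boundary_concentration(st, "A", "left") == 0.0

    def test_single_mode_right_end(self):
        b = make_basis("sine", "dirichlet", "neumann", 0, 1, 9)
        c = np.zeros(10)
        c[0] = 1.0
        st = SimulationState({"A": SpectralField.from_coefficients(b, c)})
        assert boundary_concentration(st, "A", "right") == pytest.approx(1.0)

    def test_boundary_matches_naive_synthesis(self, rng):
        b = make_basis("sine", "dirichlet", "neumann", 0, 1.7, 19)
        f = SpectralField.from_coefficients(b, rng.standard_normal(20))
        st = SimulationState({"A": f})
        assert boundary_concentration(st, "A", "right") == pytest.approx(
            synthesize_naive(f, np.array([1.7]))[0], rel=1e-12
        )

    def test_nn_inventory_is_mode_zero_times_length(self, rng):
        b = make_basis("cosine", "neumann", "neumann", 0, 2.5, 12)
        c = rng.standard_normal(13)
        st = SimulationState({"A": SpectralField.from_coefficients(b, c)})
        assert inventory(st, "A") == pytest.approx(c[0] * 2.5, rel=1e-12)

    def test_zero_field_zero_inventory(self):
        b = make_basis("sine", "dirichlet", "dirichlet", 0, 1, 6)
        st = SimulationState({"A": SpectralField(b)})
        assert inventory(st, "A") == 0.0

    def test_film_inventory_against_quadrature(self, rng):
        b = make_basis("sine", "dirichlet", "neumann", 0, 1.3, 15)
        f = SpectralField.from_coefficients(b, rng.standard_normal(16) / 10)
        st = SimulationState({"A": f})
        oracle = quadrature(lambda x: synthesize_naive(f, x), (0.0, 1.3))
        assert inventory(st, "A") == pytest.approx(oracle, rel=1e-10)


class TestFilmScan:
    def test_toy_quadratic_law_and_dose_linearity(self):
        """Source + sink with no chemistry: boundary = S L^2 / 2D exactly, so
        the log-log slope is 2 and the boundary is linear in dose rate."""
        D = 2.0
        net = zero_network(("A",), (D,))
        doses = [1.0, 2.0]
        table, slopes = scan_film(
            net, {"A": 100.0}, [0.5, 1.0, 2.0], doses, track_species="A", N=32,
        )
        for dose in doses:
            assert slopes[dose] == pytest.approx(2.0, abs=0.01)
        b1 = table[(table.dose_rate == 1.0)].set_index("L_nm").boundary_eq
        b2 = table[(table.dose_rate == 2.0)].set_index("L_nm").boundary_eq
        np.testing.assert_allclose(b2 / b1, 2.0, rtol=1e-3)
        # absolute agreement with the closed form
        S = gvalue_to_source(100.0, 1.0)
        np.testing.assert_allclose(
            b1.loc[1.0], S * 1.0**2 / (2 * D), rtol=1e-3
        )

    def test_too_few_window_points_rejected(self):
        net = zero_network(("A",), (1.0,))
        with pytest.raises(ValueError, match="3 thicknesses"):
            scan_film(net, {"A": 1.0}, [0.5, 1.0], [1.0], track_species="A")


class TestHollowing:
    def test_pure_diffusion_never_hollows(self, water_network):
        """The heat kernel preserves unimodality: no central minimum."""
        net = zero_network(("e_aq",), (4.9,))
        cfg = ScenarioConfig(
            geometry="spur", b_nm=20.0, N=96, t_end=0.5, dt0=1e-3,
            initial_gaussians={"e_aq": {"sigma": 2.3, "N0": 4.78}},
        )
        traj = run_spur(cfg, net, track_species=("e_aq",))
        onset, ratio = hollowing_metrics(traj, "e_aq")
        assert onset is None
        assert np.all(ratio > 0.98)

    def test_wide_species_consumed_by_narrow_partner_hollows(self):
        """A wide Gaussian eaten by a second-order reaction with a narrow
        partner loses most at the origin: centre/max drops immediately."""
        net = ReactionNetwork(
            [Species("wide", 1.0), Species("narrow", 1.0)],
            [Reaction(("wide", "narrow"), (), 80.0)],
        )
        cfg = ScenarioConfig(
            geometry="spur", b_nm=20.0, N=128, t_end=0.1, dt0=1e-4,
            initial_gaussians={"wide": {"sigma": 2.3, "N0": 5.0},
                               "narrow": {"sigma": 0.7, "N0": 5.0}},
        )
        traj = run_spur(cfg, net, track_species=("wide",))
        onset, ratio = hollowing_metrics(traj, "wide")
        assert onset is not None
        k = next(i for i, t in enumerate(traj.times) if t > 0)
        assert ratio[-1] < 0.9
        # initial strict decrease of the centre/max ratio
        assert np.all(np.diff(ratio[: k + 10]) < 0)


class TestSpurRobustness:
    def test_relative_g_starts_at_one_and_decreases_for_pure_consumption(self):
        """A species only consumed has inventory(t)/inventory(0) = 1 at t=0,
        non-increasing afterwards."""
        net = ReactionNetwork(
            [Species("wide", 1.0), Species("narrow", 1.0)],
            [Reaction(("wide", "narrow"), (), 80.0)],
        )
        cfg = ScenarioConfig(
            geometry="spur", b_nm=20.0, N=96, t_end=0.1, dt0=1e-4,
            initial_gaussians={"wide": {"sigma": 2.3, "N0": 5.0},
                               "narrow": {"sigma": 0.7, "N0": 5.0}},
        )
        traj = run_spur(cfg, net, track_species=("wide",))
        inv = traj.observable("inventory:wide")
        assert inv[0] / inv[0] == 1.0
        assert np.all(np.diff(inv) <= 1e-12 * inv[0])

    def test_outer_radius_insensitivity(self):
        """Doubling b (at fixed resolution) moves inventories < 1e-4 relative
        over the run window — the domain is already effectively infinite."""
        net = ReactionNetwork(
            [Species("wide", 1.0), Species("narrow", 1.0)],
            [Reaction(("wide", "narrow"), (), 80.0)],
        )
        finals = []
        for b, N in ((20.0, 96), (40.0, 192)):
            cfg = ScenarioConfig(
                geometry="spur", b_nm=b, N=N, t_end=0.05, dt0=1e-4,
                initial_gaussians={"wide": {"sigma": 2.3, "N0": 5.0},
                                   "narrow": {"sigma": 0.7, "N0": 5.0}},
            )
            traj = run_spur(cfg, net, track_species=("wide",))
            finals.append(traj.observable("inventory:wide")[-1])
        assert abs(finals[1] - finals[0]) / finals[0] < 1e-4


class TestConvergenceProtocol:
    def test_film_self_verification_reports_small_differences(
        self, water_network, alpha_gvalues
    ):
        """Halving dt and doubling N changes the equilibrium profiles by a
        small, quantified amount (both max-abs and max-relative reported)."""
        cfg = ScenarioConfig(
            thickness_nm=0.5, N=24, dt0=2e-3, dose_rate=10.0,
            g_values=alpha_gvalues, t_end=5.0,
        )
        report = convergence_report(cfg, water_network)
        assert set(report) == {"max_abs_difference", "max_rel_difference"}
        assert 0 < report["max_rel_difference"] < 0.05
        assert report["max_abs_difference"] > 0
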