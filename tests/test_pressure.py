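"""Pressure solver: manufactured solutions, fluxes, conservation, bounds."""

import numpy as np
import pytest

from glymphsim import fem
from glymphsim.geometry import synthetic_brain_mesh
from glymphsim.model import (ModelError, ModelSpec, PressureBC,
                             build_test_case)
from glymphsim.params import baseline_table
from glymphsim.pressure import (boundary_flux, exchange_flux, pore_velocity,
                                solve_pressure, velocity_stats)
from glymphsim.units import mmhg_to_pa

from conftest import BRAIN_VOLUME, SPHERE_RADIUS


def single_compartment_spec(kappa=1e-5, bc=None):
    """A one-compartment pressure problem on the e network."""
    table = baseline_table(1)
    table.kappa["e"] = kappa
    spec = ModelSpec(
        test_case=1, compartments=("e",), edges=[], table=table,
        pressure_bcs={"e": bc or PressureBC.dirichlet(100.0)},
        concentration_mode={"e": "sas_coupled"})
    return spec.validate()


class TestEquilibria:
    def test_equal_dirichlet_gives_constant_fields(self, sphere8):
        """Coupled compartments pinned to the same boundary value stay flat."""
        table = baseline_table(2)
        value = mmhg_to_pa(3.26)
        bcs = {j: PressureBC.dirichlet(value) for j in table.compartments}
        spec = build_test_case(2, table=table, overrides=bcs)
        sol = solve_pressure(spec, sphere8)
        for j in spec.compartments:
            assert np.abs(sol.p[j] - value).max() < 1e-8 * value
            assert np.abs(sol.velocity(j)).max() < 1e-12

    def test_robin_no_source_relaxes_to_external(self, sphere8):
        spec = single_compartment_spec(
            bc=PressureBC.robin(3.13e-7, 434.63))
        sol = solve_pressure(spec, sphere8)
        assert np.abs(sol.p["e"] - 434.63).max() < 1e-6


class TestManufactured:
    def prescribe(self, mesh, beta):
        """p* = x^2 + 2y^2 + 3z^2; -div(beta grad p*) = -12 beta."""
        x = mesh.vertices
        return x[:, 0] ** 2 + 2 * x[:, 1] ** 2 + 3 * x[:, 2] ** 2, -12.0 * beta

    def solve_with_source(self, mesh, kappa):
        table = baseline_table(1)
        table.kappa["e"] = kappa
        beta = kappa * table.phi["e"] / table.mu["e"]
        p_star, f = self.prescribe(mesh, beta)

        K = fem.stiffness_matrix(mesh, beta)
        rhs = f * fem.lumped_mass(mesh)
        system = fem.DirichletSystem(K, mesh.boundary_vertices)
        p_h = system.solve(rhs, p_star[mesh.boundary_vertices])
        lump = fem.lumped_mass(mesh)
        err = p_h - p_star
        return np.sqrt(float(lump @ err**2) / mesh.volume)

    def test_second_order_l2_convergence(self, sphere6):
        mesh12 = synthetic_brain_mesh(BRAIN_VOLUME, "sphere", 12)
        e6 = self.solve_with_source(sphere6, 1e-5)
        e12 = self.solve_with_source(mesh12, 1e-5)
        assert e6 / e12 > 3.0          # O(h^2): factor ~4 per halving


class TestVelocity:
    def test_constant_pressure_zero_velocity(self, sphere8, spec2):
        p = np.full(sphere8.n_vertices, 500.0)
        u = pore_velocity(sphere8, p, spec2, "e")
        assert np.abs(u).max() < 1e-12

    def test_linear_pressure_closed_form(self, sphere8, spec2):
        g = 7.5   # Pa/mm along x
        p = g * sphere8.vertices[:, 0]
        u = pore_velocity(sphere8, p, spec2, "pa")
        t = spec2.table
        expected = t.kappa["pa"] / (t.phi["pa"] * t.mu["pa"]) * g
        assert np.allclose(u[:, 0], -expected)
        assert np.abs(u[:, 1:]).max() < 1e-12
        u_aver, u_max = velocity_stats(u, sphere8)
        assert u_aver == pytest.approx(expected, rel=1e-10)
        assert u_max == pytest.approx(expected, rel=1e-10)

    def test_velocity_stats_zero_field(self, sphere8):
        u_aver, u_max = velocity_stats(np.zeros((sphere8.n_cells, 3)),
                                       sphere8)
        assert (u_aver, u_max) == (0.0, 0.0)


class TestFluxes:
    @pytest.fixture(scope="class")
    def solution(self, sphere8):
        return solve_pressure(build_test_case(2), sphere8)

    def test_exchange_flux_of_equal_fields_is_zero(self, sphere8):
        spec = build_test_case(2)
        sol = solve_pressure(spec, sphere8)
        sol.p["pa"] = sol.p["e"].copy()
        assert exchange_flux(sol, "pa", "e") == pytest.approx(0.0, abs=1e-12)

    def test_exchange_flux_constant_integrand(self, solution, sphere8):
        solution_ = solution
        p_backup = {j: solution_.p[j].copy() for j in solution_.p}
        solution_.p["pa"] = np.zeros(sphere8.n_vertices) + 1.0
        solution_.p["e"] = np.zeros(sphere8.n_vertices)
        gamma = solution_.spec.table.gamma("pa", "e")
        q = exchange_flux(solution_, "pa", "e")
        assert q == pytest.approx(gamma * sphere8.volume, rel=1e-12)
        solution_.p.update(p_backup)

    def test_exchange_flux_antisymmetry(self, solution):
        q_ji = exchange_flux(solution, "pa", "e")
        q_ij = exchange_flux(solution, "e", "pa")
        assert q_ji == pytest.approx(-q_ij, rel=1e-12)

    def test_exchange_flux_unknown_pair(self, solution):
        with pytest.raises(ModelError):
            exchange_flux(solution, "pa", "pv")

    def test_neumann_boundary_flux_recovered(self, sphere8):
        """A prescribed total influx B appears as Q_out = -B exactly."""
        table = baseline_table(3)
        spec = build_test_case(3, table=table)
        sol = solve_pressure(spec, sphere8)
        assert boundary_flux(sol, "a") == pytest.approx(-table.b_blood)
        assert boundary_flux(sol, "pc") == pytest.approx(0.0)

    def test_phi_weighted_flux_convention(self, solution):
        q_darcy = boundary_flux(solution, "e", convention="darcy")
        q_phi = boundary_flux(solution, "e", convention="phi_weighted")
        phi_e = solution.spec.table.phi["e"]
        assert q_phi == pytest.approx(q_darcy * phi_e, rel=1e-12)
        with pytest.raises(ModelError):
            boundary_flux(solution, "e", convention="bogus")

    def test_per_compartment_volume_balance(self, solution):
        """Boundary outflux Q_out,j equals the total exchange gain of
        compartment j (discrete compatibility of the assembled system)."""
        spec = solution.spec
        scale = abs(spec.table.b_flow) + 1.0
        for j in spec.compartments:
            q_out = boundary_flux(solution, j)
            gain = sum(exchange_flux(solution, e.other(j), j,
                                     include_osmotic=True)
                       for e in spec.edges_of(j))
            assert q_out == pytest.approx(gain, abs=1e-8 * scale)

    def test_dirichlet_outflux_zero_for_flat_field(self, sphere8):
        spec = single_compartment_spec(bc=PressureBC.dirichlet(250.0))
        sol = solve_pressure(spec, sphere8)
        assert abs(boundary_flux(sol, "e")) < 1e-10


class TestStructuralProperties:
    def test_robin_conductance_monotonicity(self, sphere8):
        """More pial conductance -> more flow into the periarterial space."""
        influx = []
        for factor in (0.5, 1.0, 2.0):
            table = baseline_table(2)
            table.L_pvspial_pa *= factor
            spec = build_test_case(2, table=table)
            sol = solve_pressure(spec, sphere8)
            influx.append(-boundary_flux(sol, "pa"))
        assert influx[0] < influx[1] < influx[2]
        assert influx[1] > 0   # net inflow at baseline

    def test_qualitative_maximum_principle(self, sphere8):
        """Pressures stay within the envelope of the boundary data on a
        configuration whose fields the mesh resolves (the baseline
        coefficients have micron-scale exchange layers whose Galerkin
        under/overshoots are a discretization artifact, not a solver
        property)."""
        from conftest import two_compartment_fixture
        spec, _, _, (lo, hi) = two_compartment_fixture()
        sol = solve_pressure(spec, sphere8)
        tol = 0.02 * (hi - lo)
        for j in spec.compartments:
            assert sol.p[j].min() > lo - tol
            assert sol.p[j].max() < hi + tol

    def test_iterative_matches_direct(self, sphere8, spec2):
        direct = solve_pressure(spec2, sphere8, method="direct")
        iterative = solve_pressure(spec2, sphere8, method="iterative")
        scale = mmhg_to_pa(4.74)
        for j in spec2.compartments:
            assert np.abs(direct.p[j] - iterative.p[j]).max() < 1e-6 * scale

    def test_case1_has_no_pressure_problem(self, sphere8):
        with pytest.raises(ModelError):
            solve_pressure(build_test_case(1), sphere8)
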