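"""Finite-volume transport solver: analytic limits, the Graetz oracle,
grid convergence, monotonicity, failure modes."""

import numpy as np
import pytest

from oxyflux.channel import (ChannelGeometry, build_grid, plug_profile,
                             poiseuille_profile)
from oxyflux.closures import CoupledClosure, LinearTracerClosure
from oxyflux.parameters import ParameterError
from oxyflux.solver import (BoundaryConditions, SolverSettings,
                            graetz_reference, solve_coupled)


def mixed_cup(field, velocity, grid, i=-1):
    w = velocity.u[i] * grid.dy
    return float((field[i] * w).sum() / w.sum())


class TestTrivialSolutions:
    def test_wall_equal_inlet_gives_uniform_fields(self):
        geo = ChannelGeometry(length=0.01, half_gap=1e-4)
        g = build_grid(geo, 16, 8)
        v = plug_profile(g, 0.01)
        bc = BoundaryConditions(po2_inlet=50, pco2_inlet=40,
                                po2_wall=50, pco2_wall=40)
        sol = solve_coupled(g, v, bc, SolverSettings(),
                            LinearTracerClosure())
        np.testing.assert_allclose(sol.PO2, 50.0, atol=1e-10)
        np.testing.assert_allclose(sol.PCO2, 40.0, atol=1e-10)
        assert sol.converged

    def test_zero_velocity_pure_diffusion_reaches_wall_value(self):
        # with no through-flow and a symmetry centerline, steady diffusion
        # equilibrates the whole slab with the wall
        geo = ChannelGeometry(length=0.005, half_gap=1e-4)
        g = build_grid(geo, 10, 12)
        v = plug_profile(g, 0.0)
        bc = BoundaryConditions(po2_inlet=50, pco2_inlet=40,
                                po2_wall=100, pco2_wall=10)
        sol = solve_coupled(g, v, bc, SolverSettings(axial_diffusion=False),
                            LinearTracerClosure())
        np.testing.assert_allclose(sol.PO2, 100.0, rtol=1e-5)
        np.testing.assert_allclose(sol.PCO2, 10.0, rtol=1e-4)

    def test_uniform_coupled_state(self):
        # the full physiology closure must also preserve a uniform state
        geo = ChannelGeometry(length=0.004, half_gap=1e-4)
        g = build_grid(geo, 10, 6)
        v = poiseuille_profile(g, 0.005)
        bc = BoundaryConditions(po2_inlet=35.9, pco2_inlet=44.0,
                                po2_wall=35.9, pco2_wall=44.0)
        sol = solve_coupled(g, v, bc, SolverSettings(), CoupledClosure())
        np.testing.assert_allclose(sol.PO2, 35.9, rtol=1e-8)
        np.testing.assert_allclose(sol.PCO2, 44.0, rtol=1e-8)


class TestGraetzBenchmark:
    D, U, H, L = 1e-9, 0.01, 1e-4, 0.02

    def _solve(self, nx, ny):
        geo = ChannelGeometry(length=self.L, half_gap=self.H)
        g = build_grid(geo, nx, ny)
        v = plug_profile(g, self.U)
        bc = BoundaryConditions(po2_inlet=1.0, pco2_inlet=1.0,
                                po2_wall=0.0, pco2_wall=0.0)
        sol = solve_coupled(g, v, bc,
                            SolverSettings(axial_diffusion=False, tol=1e-10,
                                           relax=1.0),
                            LinearTracerClosure(D_o2=self.D, D_co2=self.D))
        return mixed_cup(sol.PO2, v, g)

    def test_outlet_decay_matches_series(self):
        pe = self.U * self.H / self.D
        exact, trunc = graetz_reference(pe, self.L, self.H, 60)
        assert trunc < 1e-12
        num = self._solve(200, 40)
        assert num == pytest.approx(exact, rel=0.02)

    def test_observed_order_between_one_and_two(self):
        pe = self.U * self.H / self.D
        exact, _ = graetz_reference(pe, self.L, self.H, 60)
        errs = [abs(self._solve(nx, ny) - exact)
                for nx, ny in [(50, 10), (100, 20), (200, 40)]]
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        for p in orders:
            assert 1.0 <= p <= 2.0


class TestGraetzSeries:
    def test_limits(self):
        # at zero length the series converges algebraically to 1
        val, trunc = graetz_reference(100.0, 0.0, 1e-4, 200)
        assert val == pytest.approx(1.0, abs=5e-3)
        assert graetz_reference(100.0, 0.0, 1e-4, 800)[0] > val
        assert graetz_reference(100.0, 10.0, 1e-4, 50)[0] == pytest.approx(
            0.0, abs=1e-12)

    def test_terms_decay(self):
        xi_small = 1e-3
        k = np.arange(1, 40)
        lam = (2 * k - 1) * np.pi / 2
        terms = 2 / lam ** 2 * np.exp(-lam ** 2 * xi_small)
        assert (np.diff(terms[3:]) < 0).all()

    def test_too_few_terms_rejected(self):
        with pytest.raises(ParameterError):
            graetz_reference(10.0, 0.01, 1e-4, 5)


class TestFieldProperties:
    def test_monotone_transverse_fields_linear_closure(self):
        geo = ChannelGeometry(length=0.008, half_gap=1e-4)
        g = build_grid(geo, 40, 16, grading=1.1)
        v = poiseuille_profile(g, 0.005)
        bc = BoundaryConditions(po2_inlet=35.9, pco2_inlet=44.0,
                                po2_wall=700.0, pco2_wall=0.0)
        sol = solve_coupled(g, v, bc, SolverSettings(tol=1e-8),
                            LinearTracerClosure(D_o2=5e-10, D_co2=5e-10))
        # wall at j=0: PO2 maximal at wall, PCO2 minimal at wall
        assert (np.diff(sol.PO2, axis=1) <= 1e-9).all()
        assert (np.diff(sol.PCO2, axis=1) >= -1e-9).all()
        # bounded by boundary data
        assert sol.PO2.max() <= 700.0 + 1e-6
        assert sol.PO2.min() >= 35.9 - 1e-6

    def test_coupled_fields_bounded_and_near_monotone(self, coupled_solution):
        sol = coupled_solution
        assert sol.converged
        assert sol.PO2.max() <= sol.bc.po2_wall + 1e-6
        assert sol.PCO2.max() <= sol.bc.pco2_inlet + 1e-6
        assert sol.PCO2.min() >= 0.0
        # PCO2 strictly monotone toward the stripping wall
        assert (np.diff(sol.PCO2, axis=1) >= -1e-9).all()
        # PO2 monotone up to the small Bohr dip from the coupled content
        viol = np.diff(sol.PO2, axis=1)
        assert viol.max() <= 0.05 * sol.bc.po2_inlet

    def test_robin_wall_weaker_than_dirichlet(self):
        geo = ChannelGeometry(length=0.008, half_gap=1e-4)
        g = build_grid(geo, 30, 12, grading=1.1)
        v = poiseuille_profile(g, 0.005)
        common = dict(po2_inlet=35.9, pco2_inlet=44.0,
                      po2_wall=707.7, pco2_wall=0.0)
        closure = CoupledClosure()
        dir_sol = solve_coupled(g, v, BoundaryConditions(**common),
                                SolverSettings(), closure)
        rob_sol = solve_coupled(
            g, v, BoundaryConditions(wall_mode="robin_membrane", **common),
            SolverSettings(), closure)

        def content_out(sol):
            return mixed_cup(np.asarray(closure.o2_content(sol.PO2, sol.PCO2)),
                             v, g)
        # extra membrane resistance lowers O2 uptake and CO2 removal
        assert content_out(rob_sol) <= content_out(dir_sol)
        assert mixed_cup(rob_sol.PCO2, v, g) >= mixed_cup(dir_sol.PCO2, v, g)
        # membrane resistance is small compared to the blood-side layer
        assert content_out(rob_sol) > 0.8 * content_out(dir_sol)


class TestFailureModes:
    def test_iteration_cap_flags_unconverged(self):
        geo = ChannelGeometry(length=0.008, half_gap=1e-4)
        g = build_grid(geo, 20, 8)
        v = poiseuille_profile(g, 0.005)
        sol = solve_coupled(g, v, BoundaryConditions(),
                            SolverSettings(max_outer=2), CoupledClosure())
        assert not sol.converged
        assert sol.warnings

    def test_velocity_grid_mismatch_rejected(self):
        geo = ChannelGeometry(length=0.008, half_gap=1e-4)
        g = build_grid(geo, 20, 8)
        g2 = build_grid(geo, 10, 8)
        v = plug_profile(g2, 0.005)
        with pytest.raises(ParameterError):
            solve_coupled(g, v, BoundaryConditions(), SolverSettings(),
                          LinearTracerClosure())

    def test_settings_validation(self):
        with pytest.raises(ParameterError):
            SolverSettings(relax=0.0)
        with pytest.raises(ParameterError):
            SolverSettings(tol=-1.0)
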