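"""Shared fixtures: default parameter sets and a coarse solved channel."""

import numpy as np
import pytest

from oxyflux import (BloodParameters, BoundaryConditions, ChannelGeometry,
                     CoupledClosure, GasTransportConstants, SolverSettings,
                     build_grid, poiseuille_profile, solve_coupled)


@pytest.fixture(scope="session")
def params():
    return BloodParameters()


@pytest.fixture(scope="session")
def constants():
    return GasTransportConstants()


@pytest.fixture(scope="session")
def coarse_channel():
    """Coarse reference-channel grid and velocity (100 mL/min condition)."""
    geo = ChannelGeometry(length=0.016, half_gap=90e-6)
    grid = build_grid(geo, 48, 20, grading=1.1)
    velocity = poiseuille_profile(grid, 0.0034)
    return grid, velocity


@pytest.fixture(scope="session")
def coupled_solution(coarse_channel, params, constants):
    """Converged coupled solve on the coarse reference channel."""
    grid, velocity = coarse_channel
    return solve_coupled(grid, velocity, BoundaryConditions(),
                         SolverSettings(), CoupledClosure(params, constants),
                         params, constants)


@pytest.fixture(scope="session")
def physiological_grid():
    """20-state (PO2, PCO2) grid spanning the physiological range."""
    po2 = np.array([10.0, 25.0, 35.9, 60.0, 100.0])
    pco2 = np.array([15.0, 30.0, 44.0, 70.0])
    pp, cc = np.meshgrid(po2, pco2)
    return pp.ravel(), cc.ravel()
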