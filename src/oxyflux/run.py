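"""Config-driven simulation driver: RunConfig -> solved fields + report."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import physiology as phys
from .channel import build_grid, plug_profile, poiseuille_profile, velocity_from_csv
from .closures import make_closure
from .config import RunConfig
from .reporting import TransferReport, build_report
from .solver import FieldSolution, solve_coupled

__all__ = ["run_simulation", "fields_frame"]


def run_simulation(config: RunConfig | None = None
                   ) -> tuple[FieldSolution, TransferReport]:
    """Build every model object from a configuration and solve the channel."""
    cfg = config or RunConfig()
    params = cfg.blood.build()
    constants = cfg.gas_constants.build()
    membrane = cfg.membrane.build()
    geometry = cfg.geometry.build()
    grid = build_grid(geometry, cfg.grid.Nx, cfg.grid.Ny, cfg.grid.grading)
    if cfg.velocity.profile == "plug":
        velocity = plug_profile(grid, cfg.velocity.mean_velocity)
    elif cfg.velocity.profile == "poiseuille":
        velocity = poiseuille_profile(grid, cfg.velocity.mean_velocity)
    else:
        velocity = velocity_from_csv(cfg.velocity.csv_path, grid)
    bc = cfg.boundary.build(membrane)
    settings = cfg.solver.build()
    closure = make_closure(cfg.closure, params, constants)
    solution = solve_coupled(grid, velocity, bc, settings, closure,
                             params, constants, symmetry=geometry.symmetry)
    report = build_report(solution, width=cfg.geometry.width)
    return solution, report


def fields_frame(solution: FieldSolution) -> pd.DataFrame:
    """Cell-centered solution fields as a tidy DataFrame (x fastest)."""
    grid = solution.grid
    xc, yc = grid.xc, grid.yc
    yy, xx = np.meshgrid(yc, xc)
    return pd.DataFrame({
        "x_m": xx.T.ravel(),
        "y_m": yy.T.ravel(),
        "po2_mmhg": solution.PO2.T.ravel(),
        "pco2_mmhg": solution.PCO2.T.ravel(),
        "so2": solution.SO2.T.ravel(),
        "ph": solution.pH.T.ravel(),
        "c_o2_ml_ml": solution.C_O2.T.ravel(),
        "c_co2_ml_ml": solution.C_CO2.T.ravel(),
    })


def write_vtk(solution: FieldSolution, path: str | Path) -> None:
    """Legacy-ASCII structured-grid VTK export of the solved fields."""
    grid = solution.grid
    nx, ny = grid.Nx, grid.Ny
    lines = [
        "# vtk DataFile Version 3.0",
        "oxyflux channel solution",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx} {ny} 1",
        f"X_COORDINATES {nx} double",
        " ".join(f"{x:.9e}" for x in grid.xc),
        f"Y_COORDINATES {ny} double",
        " ".join(f"{y:.9e}" for y in grid.yc),
        "Z_COORDINATES 1 double",
        "0.0",
        f"POINT_DATA {nx * ny}",
    ]
    for name, field in (("PO2", solution.PO2), ("PCO2", solution.PCO2),
                        ("SO2", solution.SO2), ("pH", solution.pH)):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(" ".join(f"{v:.9e}" for v in field.T.ravel()))
    Path(path).write_text("\n".join(lines) + "\n")
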