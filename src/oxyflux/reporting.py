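"""Flow-weighted averaging, transfer rates and conservation diagnostics.

Bulk ("mixed-cup") quantities are velocity-weighted cross-sectional means —
the thermodynamically meaningful averages for convected scalars.  Transfer
rates follow the content bookkeeping of the transport model:

    mdot_O2  = Q * 1e3 * [ alpha_O2 (PO2_out - PO2_in)
                           + k_O2 Hb (SO2_out - SO2_in) ]      (mL O2/min)
    mdot_CO2 = Q * 1e3 * ( C_CO2_in - C_CO2_out )              (mL CO2/min)

with Q the blood flow in L/min, O2 content from the dissolved + bound pools
and total CO2 content from the McHardy formula.  Removal of CO2 is positive
(in minus out); O2 uptake is positive (out minus in).

The conservation diagnostic compares the integrated diffusive wall flux
with the mixed-cup change of the *convected* content of the closure that
produced the solution (for the coupled closure, the same three-pool
content whose slopes weight the effective diffusivity), which is the pair
the discrete scheme actually balances.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import physiology as phys
from .parameters import BloodParameters, GasTransportConstants, ParameterError
from .solver import FieldSolution

__all__ = [
    "TransferReport",
    "flow_weighted_average",
    "o2_transfer_rate",
    "co2_transfer_rate",
    "wall_flux",
    "axial_profiles",
    "build_report",
    "closure_comparison",
]

ML_PER_M3 = 1e6
S_PER_MIN = 60.0


class AveragingError(ValueError):
    """Raised when a flow-weighted average is undefined (zero flux)."""


@dataclass
class TransferReport:
    """Flow-weighted inlet/outlet state, transfer rates and diagnostics."""

    closure: str
    Q_blood_ml_min: float
    po2_in: float
    po2_out: float
    pco2_in: float
    pco2_out: float
    so2_in: float
    so2_out: float
    c_o2_in: float
    c_o2_out: float
    c_co2_in: float
    c_co2_out: float
    mdot_o2_ml_min: float
    mdot_co2_ml_min: float
    wall_flux_o2_ml_min: float
    wall_flux_co2_ml_min: float
    conservation_error_o2: float
    conservation_error_co2: float
    converged: bool
    n_clamped: int
    warnings: list

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        """Aligned human-readable table."""
        rows = [
            ("closure", self.closure),
            ("Q blood [mL/min]", f"{self.Q_blood_ml_min:.4g}"),
            ("PO2 in/out [mmHg]", f"{self.po2_in:.2f} / {self.po2_out:.2f}"),
            ("PCO2 in/out [mmHg]", f"{self.pco2_in:.2f} / {self.pco2_out:.2f}"),
            ("SO2 in/out [-]", f"{self.so2_in:.4f} / {self.so2_out:.4f}"),
            ("C_O2 in/out [mL/mL]", f"{self.c_o2_in:.5f} / {self.c_o2_out:.5f}"),
            ("C_CO2 in/out [mL/mL]", f"{self.c_co2_in:.5f} / {self.c_co2_out:.5f}"),
            ("O2 transfer [mL/min]", f"{self.mdot_o2_ml_min:.5g}"),
            ("CO2 removal [mL/min]", f"{self.mdot_co2_ml_min:.5g}"),
            ("wall flux O2 [mL/min]", f"{self.wall_flux_o2_ml_min:.5g}"),
            ("wall flux CO2 [mL/min]", f"{self.wall_flux_co2_ml_min:.5g}"),
            ("conservation err O2", f"{self.conservation_error_o2:.2e}"),
            ("conservation err CO2", f"{self.conservation_error_co2:.2e}"),
            ("converged", str(self.converged)),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def flow_weighted_average(field: np.ndarray, velocity, grid,
                          station: int) -> float:
    """Mixed-cup average of a cell field over the cross-section at an axial
    station (cell-column index; negative indices count from the outlet)."""
    u = velocity.u[station]
    phi = np.asarray(field)[station]
    w = u * grid.dy
    total = w.sum()
    if total <= 0:
        raise AveragingError("flow-weighted average undefined: zero total flux")
    return float((phi * w).sum() / total)


def o2_transfer_rate(Q_l_min: float, po2_in: float, po2_out: float,
                     so2_in: float, so2_out: float,
                     params: BloodParameters | None = None,
                     constants: GasTransportConstants | None = None) -> float:
    """O2 transfer rate (mL O2/min) from mixed-cup inlet/outlet averages."""
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    return Q_l_min * 1e3 * (constants.alpha_O2 * (po2_out - po2_in)
                            + constants.k_O2 * params.Hb * (so2_out - so2_in))


def co2_transfer_rate(Q_l_min: float, c_in: float, c_out: float) -> float:
    """CO2 removal rate (mL CO2/min), positive when outlet content is lower."""
    return Q_l_min * 1e3 * (c_in - c_out)


def _wall_flux_columns(solution: FieldSolution, species: str,
                       width: float) -> np.ndarray:
    """Per-column diffusive wall flux (mL gas STP/min), positive into blood."""
    grid, bc, cl = solution.grid, solution.bc, solution.closure
    params = solution.params
    dy0 = grid.dy[0]
    if species == "O2":
        gam_cell, _, _ = cl.o2_fields(solution.PO2[:, 0], solution.PCO2[:, 0])
        gam_wall, _, _ = cl.o2_fields(bc.po2_wall,
                                      max(bc.pco2_wall, params.pco2_floor))
        p_wall, p_cell = bc.po2_wall, solution.PO2[:, 0]
    elif species == "CO2":
        gam_cell, _, _ = cl.co2_fields(solution.PCO2[:, 0], solution.PO2[:, 0])
        gam_wall, _, _ = cl.co2_fields(max(bc.pco2_wall, params.pco2_floor),
                                       bc.po2_wall)
        p_wall, p_cell = bc.pco2_wall, solution.PCO2[:, 0]
    else:
        raise ParameterError(f"unknown species {species!r}")
    gam_cell = np.asarray(gam_cell, float)
    gam_wall = float(np.asarray(gam_wall))
    if bc.wall_mode == "dirichlet":
        g_face = 2.0 * gam_cell * gam_wall / (gam_cell + gam_wall)
        flux_per_area = g_face * (p_wall - p_cell) / (0.5 * dy0)
    else:
        from .membrane import wall_permeance
        perm = wall_permeance(bc.membrane, species, bc.wall_T) * 1e-2
        resist = 1.0 / perm + 0.5 * dy0 / gam_cell
        flux_per_area = (p_wall - p_cell) / resist
    cols = flux_per_area * grid.dx * width * ML_PER_M3 * S_PER_MIN
    if not solution.symmetry:
        # mirrored membrane wall at y = half_gap
        if species == "O2":
            gam_top, _, _ = cl.o2_fields(solution.PO2[:, -1], solution.PCO2[:, -1])
            p_top = solution.PO2[:, -1]
        else:
            gam_top, _, _ = cl.co2_fields(solution.PCO2[:, -1], solution.PO2[:, -1])
            p_top = solution.PCO2[:, -1]
        gam_top = np.asarray(gam_top, float)
        if bc.wall_mode == "dirichlet":
            g_face = 2.0 * gam_top * gam_wall / (gam_top + gam_wall)
            fpa = g_face * (p_wall - p_top) / (0.5 * grid.dy[-1])
        else:
            from .membrane import wall_permeance
            perm = wall_permeance(bc.membrane, species, bc.wall_T) * 1e-2
            fpa = (p_wall - p_top) / (1.0 / perm + 0.5 * grid.dy[-1] / gam_top)
        cols = cols + fpa * grid.dx * width * ML_PER_M3 * S_PER_MIN
    return cols


def wall_flux(solution: FieldSolution, species: str,
              width: float = 0.01) -> float:
    """Integrated diffusive wall flux of a species (mL gas STP/min).

    Positive into the blood; under default boundary data O2 flux is
    positive and CO2 flux negative (CO2 leaves).  ``width`` is the channel
    depth (m) used to convert per-depth fluxes to absolute rates.
    """
    total = float(_wall_flux_columns(solution, species, width).sum())
    return total


def _blood_flow(solution: FieldSolution, width: float) -> float:
    """Volumetric blood flow through the channel cross-section, m^3/s."""
    return float((solution.velocity.u[0] * solution.grid.dy).sum() * width)


def build_report(solution: FieldSolution, width: float = 0.01,
                 co2_variant: str = "kelman_grouping") -> TransferReport:
    """Assemble the transfer report for a solved channel.

    Mixed-cup inlet averages use the prescribed inlet state (the upwind
    value actually convected in); outlet averages are taken at the exit
    cell column.
    """
    grid, v, bc = solution.grid, solution.velocity, solution.bc
    params, constants, cl = solution.params, solution.constants, solution.closure
    warnings = list(solution.warnings)
    if not solution.converged:
        warnings.append("solution not converged: report values are approximate")

    q_m3s = _blood_flow(solution, width)
    q_ml_min = q_m3s * ML_PER_M3 * S_PER_MIN
    q_l_min = q_ml_min / 1e3

    po2_in, pco2_in = bc.po2_inlet, bc.pco2_inlet
    po2_out = flow_weighted_average(solution.PO2, v, grid, -1)
    pco2_out = flow_weighted_average(solution.PCO2, v, grid, -1)

    if cl.tag == "frozen_o2_curve":
        so2_in = float(np.asarray(cl.o2_saturation(po2_in)))
        so2_out = flow_weighted_average(
            np.asarray(cl.o2_saturation(solution.PO2)), v, grid, -1)
    else:
        so2_in = phys.so2(po2_in, pco2_in, params, constants)
        so2_out = flow_weighted_average(solution.SO2, v, grid, -1)

    # reported (physiological) contents: Eq-style O2 pools and McHardy CO2
    c_o2_in = phys.o2_content(po2_in, pco2_in, params, constants)
    c_o2_out = flow_weighted_average(
        np.asarray(phys.o2_content(solution.PO2, solution.PCO2,
                                   params, constants)), v, grid, -1)
    c_co2_in = phys.co2_content(pco2_in, po2_in, params, constants,
                                variant=co2_variant)
    c_co2_out = flow_weighted_average(
        np.asarray(phys.co2_content(solution.PCO2, solution.PO2, params,
                                    constants, variant=co2_variant)),
        v, grid, -1)

    mdot_o2 = o2_transfer_rate(q_l_min, po2_in, po2_out, so2_in, so2_out,
                               params, constants)
    mdot_co2 = co2_transfer_rate(q_l_min, c_co2_in, c_co2_out)

    # conservation: closure-consistent convected content vs wall flux
    wf_o2 = wall_flux(solution, "O2", width)
    wf_co2 = wall_flux(solution, "CO2", width)
    conv_o2 = q_l_min * 1e3 * (
        flow_weighted_average(np.asarray(cl.o2_content(solution.PO2,
                                                       solution.PCO2)),
                              v, grid, -1)
        - float(np.asarray(cl.o2_content(po2_in, pco2_in))))
    conv_co2 = q_l_min * 1e3 * (
        flow_weighted_average(np.asarray(cl.co2_content(solution.PCO2,
                                                        solution.PO2)),
                              v, grid, -1)
        - float(np.asarray(cl.co2_content(pco2_in, po2_in))))
    tiny = 1e-30
    err_o2 = abs(wf_o2 - conv_o2) / max(abs(wf_o2), tiny)
    err_co2 = abs(wf_co2 - conv_co2) / max(abs(wf_co2), tiny)

    return TransferReport(
        closure=cl.tag, Q_blood_ml_min=q_ml_min,
        po2_in=po2_in, po2_out=po2_out, pco2_in=pco2_in, pco2_out=pco2_out,
        so2_in=so2_in, so2_out=so2_out,
        c_o2_in=c_o2_in, c_o2_out=c_o2_out,
        c_co2_in=c_co2_in, c_co2_out=c_co2_out,
        mdot_o2_ml_min=mdot_o2, mdot_co2_ml_min=mdot_co2,
        wall_flux_o2_ml_min=wf_o2, wall_flux_co2_ml_min=wf_co2,
        conservation_error_o2=err_o2, conservation_error_co2=err_co2,
        converged=solution.converged, n_clamped=solution.n_clamped,
        warnings=warnings,
    )


def axial_profiles(solution: FieldSolution, n_segments: int = 8,
                   width: float = 0.01, co2_variant: str = "kelman_grouping"
                   ) -> pd.DataFrame:
    """Per-segment transfer rates along the channel.

    The channel is split into ``n_segments`` contiguous axial blocks; each
    segment's transfer is the mixed-cup content-flow difference between its
    downstream and upstream faces (inlet face uses the prescribed inlet
    state), so segments sum exactly to the whole-channel totals.
    """
    if n_segments < 1:
        raise ParameterError("n_segments must be at least 1")
    grid, v = solution.grid, solution.velocity
    params, constants = solution.params, solution.constants
    q_l_min = _blood_flow(solution, width) * ML_PER_M3 * S_PER_MIN / 1e3

    bounds = np.linspace(0, grid.Nx, n_segments + 1).astype(int)
    bounds = np.unique(bounds)
    c_o2 = np.asarray(phys.o2_content(solution.PO2, solution.PCO2,
                                      params, constants))
    c_co2 = np.asarray(phys.co2_content(solution.PCO2, solution.PO2,
                                        params, constants, variant=co2_variant))

    def station_avg(field, i_face):
        """Mixed-cup value at the upstream side of cell column i_face."""
        if i_face == 0:
            return None  # inlet: prescribed state
        return flow_weighted_average(field, v, grid, i_face - 1)

    rows = []
    c_o2_in = phys.o2_content(solution.bc.po2_inlet, solution.bc.pco2_inlet,
                              params, constants)
    c_co2_in = phys.co2_content(solution.bc.pco2_inlet, solution.bc.po2_inlet,
                                params, constants, variant=co2_variant)
    for s in range(len(bounds) - 1):
        i0, i1 = bounds[s], bounds[s + 1]
        up_o2 = c_o2_in if i0 == 0 else station_avg(c_o2, i0)
        up_co2 = c_co2_in if i0 == 0 else station_avg(c_co2, i0)
        dn_o2 = station_avg(c_o2, i1)
        dn_co2 = station_avg(c_co2, i1)
        rows.append({
            "segment": s,
            "x_start": grid.x_faces[i0],
            "x_end": grid.x_faces[i1],
            "mdot_o2_ml_min": q_l_min * 1e3 * (dn_o2 - up_o2),
            "mdot_co2_ml_min": q_l_min * 1e3 * (up_co2 - dn_co2),
        })
    return pd.DataFrame(rows)


def closure_comparison(solutions: dict[str, FieldSolution],
                       width: float = 0.01) -> pd.DataFrame:
    """Side-by-side closure comparison on shared grid and boundary data.

    Rows per closure: outlet contents, transfer rates and the Deff metadata
    (whether the CO2 diffusivity depends on the local state).  Raises if
    the solutions do not share a grid.
    """
    if not solutions:
        raise ParameterError("no solutions to compare")
    grids = {id(s.grid) for s in solutions.values()}
    shapes = {(s.grid.Nx, s.grid.Ny) for s in solutions.values()}
    if len(shapes) > 1:
        raise ParameterError(f"solutions use different grids: {shapes}")
    del grids
    rows = []
    for name, sol in solutions.items():
        rep = build_report(sol, width)
        rows.append({
            "closure": name,
            "po2_out": rep.po2_out,
            "pco2_out": rep.pco2_out,
            "c_o2_out": rep.c_o2_out,
            "c_co2_out": rep.c_co2_out,
            "mdot_o2_ml_min": rep.mdot_o2_ml_min,
            "mdot_co2_ml_min": rep.mdot_co2_ml_min,
            "deff_co2_state_dependent": sol.closure.tag != "constant_co2_slope",
            "converged": rep.converged,
        })
    df = pd.DataFrame(rows).set_index("closure")
    if "coupled" in df.index:
        for col in ("c_o2_out", "c_co2_out", "mdot_o2_ml_min",
                    "mdot_co2_ml_min"):
            df[f"{col}_minus_coupled"] = df[col] - df.loc["coupled", col]
    return df
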