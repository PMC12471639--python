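"""Steady finite-volume solver for coupled O2/CO2 transport in the channel.

The physics is the steady conservation law for each gas,

    div( u * C_s(P) ) = div( Gamma_s(P) * grad P ),

where C_s is the total carried content of species s and Gamma_s its
diffusive content-flux coefficient (both supplied by a closure).  Dividing
this law by the content slope dC/dP yields the familiar one-field pressure
equation with the capacity-weighted effective diffusivity; the solver works
on the undivided form because it is discretely conservative: the sum of the
cell balances telescopes to boundary fluxes, so the integrated wall flux
matches the mixed-cup content change to solver tolerance regardless of how
strongly the content slope varies across the O2 boundary layer.

Discretization: first-order upwind convection of the content (Picard
secant linearization ``C(P) ~ C(P_k) + dC/dP|_k (P - P_k)``), central
diffusion with harmonic-mean face flux coefficients, Dirichlet inlet,
convective outflow, Dirichlet or Robin (membrane series-resistance) wall at
y = 0 and a symmetry plane (or mirrored wall) at y = half_gap.  Outer
Picard sweeps re-evaluate the closure fields with under-relaxation; within
each sweep the CO2 field is updated first and the O2 field second (each
species' closure sees the other's latest field).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import physiology as phys
from .channel import StructuredGrid, VelocityField
from .closures import Closure
from .membrane import MembraneSpec, wall_permeance
from .parameters import BloodParameters, GasTransportConstants, ParameterError

__all__ = [
    "BoundaryConditions",
    "SolverSettings",
    "FieldSolution",
    "SolverError",
    "solve_coupled",
    "graetz_reference",
]


class SolverError(RuntimeError):
    """Raised on Picard divergence; carries the residual history."""

    def __init__(self, message: str, history=None):
        super().__init__(message)
        self.history = list(history or [])


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet and wall partial pressures (mmHg).

    Defaults are the venous-inlet / gas-side values of the reference
    oxygenation problem: inlet PO2 35.9 (saturation 0.65), inlet PCO2 44,
    pure-O2 gas side 707.7 at the membrane wall, CO2 stripped to 0.
    """

    po2_inlet: float = 35.9
    pco2_inlet: float = 44.0
    wall_mode: str = "dirichlet"          # 'dirichlet' | 'robin_membrane'
    po2_wall: float = 707.7
    pco2_wall: float = 0.0
    membrane: MembraneSpec | None = None  # required for robin_membrane
    wall_T: float = 310.0                 # K, for the membrane permeance

    def __post_init__(self) -> None:
        for name in ("po2_inlet", "pco2_inlet", "po2_wall", "pco2_wall"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.wall_mode not in ("dirichlet", "robin_membrane"):
            raise ParameterError(f"unknown wall_mode {self.wall_mode!r}")
        if self.wall_mode == "robin_membrane" and self.membrane is None:
            object.__setattr__(self, "membrane", MembraneSpec())


@dataclass(frozen=True)
class SolverSettings:
    tol: float = 1e-6                 # relative field change, outer loop
    max_outer: int = 200
    relax: float = 0.7                # Picard under-relaxation
    axial_diffusion: bool = True
    linear_tol: float = 1e-12         # kept for iterative back-ends
    divergence_window: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.relax <= 1:
            raise ParameterError("relax must lie in (0, 1]")
        if self.tol <= 0 or self.linear_tol <= 0:
            raise ParameterError("tolerances must be positive")


@dataclass
class FieldSolution:
    """Converged (or flagged) PO2/PCO2 fields plus derived physiology."""

    PO2: np.ndarray
    PCO2: np.ndarray
    SO2: np.ndarray
    pH: np.ndarray
    C_O2: np.ndarray
    C_CO2: np.ndarray
    residual_history: list
    converged: bool
    n_clamped: int
    grid: StructuredGrid
    velocity: VelocityField
    bc: BoundaryConditions
    settings: SolverSettings
    closure: Closure
    params: BloodParameters
    constants: GasTransportConstants
    outer_iterations: int = 0
    symmetry: bool = True
    warnings: list = field(default_factory=list)


def _assemble_species(grid, u, p_old, gamma, slope, content, c_inlet,
                      gamma_inlet, p_inlet, p_wall, wall_coef_mode, wall_perm,
                      gamma_wall, symmetry, axial_diffusion):
    """Assemble the linearized FV system A P = b for one species.

    ``gamma``/``slope``/``content`` are cell arrays from the closure at the
    current Picard iterate; convection is upwind in +x and linearized about
    ``p_old``.
    """
    nx, ny = grid.Nx, grid.Ny
    dx, dy = grid.dx, grid.dy
    n = nx * ny

    diag = np.zeros((nx, ny))
    west = np.zeros((nx, ny))   # coupling to (i-1, j)
    east = np.zeros((nx, ny))   # coupling to (i+1, j)
    south = np.zeros((nx, ny))  # coupling to (i, j-1)
    north = np.zeros((nx, ny))  # coupling to (i, j+1)
    b = np.zeros((nx, ny))

    def harm(a, c):
        return 2.0 * a * c / (a + c)

    # --- convection (u >= 0, upwind) ---
    # east faces, i = 0..nx-2: upwind cell (i, j); outlet face i = nx-1
    u_e = np.empty((nx, ny))
    u_e[:-1] = 0.5 * (u[:-1] + u[1:])
    u_e[-1] = u[-1]
    F_e = u_e * dy[None, :]
    # out through east face, upwind = self
    diag += F_e * slope
    b += F_e * (slope * p_old - content)
    # in through west face: interior faces reuse F_e of the west neighbour
    F_w = np.zeros((nx, ny))
    F_w[1:] = F_e[:-1]
    west[1:] = -F_w[1:] * slope[:-1]
    b[1:] -= F_w[1:] * (slope[:-1] * p_old[:-1] - content[:-1])
    # inlet convective influx (Dirichlet content)
    F_in = u[0] * dy
    b[0] += F_in * c_inlet

    # --- axial diffusion ---
    if axial_diffusion:
        g_e = harm(gamma[:-1], gamma[1:])
        d_e = 0.5 * (dx[:-1, None] + dx[1:, None])
        De = g_e * dy[None, :] / d_e
        diag[:-1] += De
        east[:-1] -= De
        diag[1:] += De
        west[1:] -= De
        # inlet Dirichlet diffusive flux across half cell
        Din = harm(gamma[0], gamma_inlet) * dy / (0.5 * dx[0])
        diag[0] += Din
        b[0] += Din * p_inlet
        # outlet: zero diffusive flux

    # --- transverse diffusion ---
    g_n = harm(gamma[:, :-1], gamma[:, 1:])
    d_n = 0.5 * (dy[:-1] + dy[1:])[None, :]
    Dn = g_n * dx[:, None] / d_n
    diag[:, :-1] += Dn
    north[:, :-1] -= Dn
    diag[:, 1:] += Dn
    south[:, 1:] -= Dn

    # membrane wall at y = 0 (j = 0)
    if wall_coef_mode == "dirichlet":
        gw = harm(gamma[:, 0], gamma_wall)
        Dw = gw * dx / (0.5 * dy[0])
        diag[:, 0] += Dw
        b[:, 0] += Dw * p_wall
    else:  # robin_membrane: series resistance membrane + half cell
        resist = 1.0 / wall_perm + (0.5 * dy[0]) / gamma[:, 0]
        Dw = dx / resist
        diag[:, 0] += Dw
        b[:, 0] += Dw * p_wall

    # top boundary at y = half_gap (j = ny-1)
    if not symmetry:
        gt = harm(gamma[:, -1], gamma_wall)
        Dt = gt * dx / (0.5 * dy[-1])
        diag[:, -1] += Dt
        b[:, -1] += Dt * p_wall
    # symmetry: zero flux, nothing to add

    idx = np.arange(n).reshape(nx, ny)
    rows, cols, vals = [idx.ravel()], [idx.ravel()], [diag.ravel()]
    rows.append(idx[1:].ravel()); cols.append(idx[:-1].ravel()); vals.append(west[1:].ravel())
    rows.append(idx[:-1].ravel()); cols.append(idx[1:].ravel()); vals.append(east[:-1].ravel())
    rows.append(idx[:, 1:].ravel()); cols.append(idx[:, :-1].ravel()); vals.append(south[:, 1:].ravel())
    rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel()); vals.append(north[:, :-1].ravel())
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return A, b.ravel()


def solve_coupled(grid: StructuredGrid, velocity: VelocityField,
                  bc: BoundaryConditions | None = None,
                  settings: SolverSettings | None = None,
                  closure: Closure | None = None,
                  params: BloodParameters | None = None,
                  constants: GasTransportConstants | None = None,
                  symmetry: bool = True) -> FieldSolution:
    """Solve the coupled nonlinear PO2/PCO2 transport problem.

    Returns a :class:`FieldSolution`; raises :class:`SolverError` only on
    sustained residual growth, while hitting the iteration cap returns the
    last iterate flagged unconverged.
    """
    bc = bc or BoundaryConditions()
    settings = settings or SolverSettings()
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    closure = closure or Closure(params, constants)
    if velocity.u.shape != (grid.Nx, grid.Ny):
        raise ParameterError(
            f"velocity shape {velocity.u.shape} does not match grid "
            f"({grid.Nx}, {grid.Ny})")

    po2 = np.full((grid.Nx, grid.Ny), float(bc.po2_inlet))
    pco2 = np.full((grid.Nx, grid.Ny), float(bc.pco2_inlet))
    u = velocity.u

    if bc.wall_mode == "robin_membrane":
        perm_o2 = wall_permeance(bc.membrane, "O2", bc.wall_T) * 1e-2  # m/s/mmHg
        perm_co2 = wall_permeance(bc.membrane, "CO2", bc.wall_T) * 1e-2
    else:
        perm_o2 = perm_co2 = None

    c_in_o2 = float(np.asarray(closure.o2_content(bc.po2_inlet, bc.pco2_inlet)))
    c_in_co2 = float(np.asarray(closure.co2_content(bc.pco2_inlet, bc.po2_inlet)))
    g_in_o2 = float(np.asarray(closure.o2_flux_coeff(bc.po2_inlet, bc.pco2_inlet)))
    g_in_co2 = float(np.asarray(closure.co2_flux_coeff(bc.pco2_inlet, bc.po2_inlet)))
    # wall-side flux coefficients for Dirichlet faces
    g_wall_o2 = float(np.asarray(closure.o2_flux_coeff(bc.po2_wall, bc.pco2_wall)))
    g_wall_co2 = float(np.asarray(closure.co2_flux_coeff(
        max(bc.pco2_wall, params.pco2_floor), bc.po2_wall)))

    history: list[float] = []
    n_clamped = 0
    converged = False
    warnings: list[str] = []
    growth = 0
    it = 0
    for it in range(1, settings.max_outer + 1):
        po2_prev, pco2_prev = po2, pco2

        # CO2 first
        gam, slo, con = (np.asarray(a) for a in closure.co2_fields(pco2, po2))
        A, rhs = _assemble_species(
            grid, u, pco2, gam, slo, con, c_in_co2, g_in_co2,
            bc.pco2_inlet, bc.pco2_wall, bc.wall_mode, perm_co2, g_wall_co2,
            symmetry, settings.axial_diffusion)
        pco2_new = spla.spsolve(A, rhs).reshape(grid.Nx, grid.Ny)
        neg = pco2_new < 0
        n_clamped += int(neg.sum())
        pco2_new = np.maximum(pco2_new, 0.0)
        pco2 = settings.relax * pco2_new + (1 - settings.relax) * pco2

        # O2 second, seeing the updated CO2 field
        gam, slo, con = (np.asarray(a) for a in closure.o2_fields(po2, pco2))
        A, rhs = _assemble_species(
            grid, u, po2, gam, slo, con, c_in_o2, g_in_o2,
            bc.po2_inlet, bc.po2_wall, bc.wall_mode, perm_o2, g_wall_o2,
            symmetry, settings.axial_diffusion)
        po2_new = spla.spsolve(A, rhs).reshape(grid.Nx, grid.Ny)
        neg = po2_new < 0
        n_clamped += int(neg.sum())
        po2_new = np.maximum(po2_new, 0.0)
        po2 = settings.relax * po2_new + (1 - settings.relax) * po2

        scale = max(float(np.abs(po2_prev).max()), 1.0)
        scale_c = max(float(np.abs(pco2_prev).max()), 1.0)
        res = max(float(np.abs(po2 - po2_prev).max()) / scale,
                  float(np.abs(pco2 - pco2_prev).max()) / scale_c)
        history.append(res)
        if res <= settings.tol:
            converged = True
            break
        if len(history) > 1 and res > history[-2]:
            growth += 1
            if growth >= settings.divergence_window:
                raise SolverError(
                    f"Picard iteration diverging (residual grew {growth} "
                    f"consecutive sweeps, last {res:.3e})", history)
        else:
            growth = 0

    if not converged:
        warnings.append(
            f"outer iteration cap {settings.max_outer} reached, residual "
            f"{history[-1] if history else float('nan'):.3e}")

    state = phys.evaluate_state(po2, pco2, params, constants)
    so2_field = np.asarray(state.SO2)
    if isinstance(closure, Closure) and closure.tag == "frozen_o2_curve":
        so2_field = np.asarray(closure.o2_saturation(po2))
    return FieldSolution(
        PO2=po2, PCO2=pco2, SO2=so2_field, pH=np.asarray(state.pH),
        C_O2=np.asarray(closure.o2_content(po2, pco2)),
        C_CO2=np.asarray(closure.co2_content(pco2, po2)),
        residual_history=history, converged=converged,
        n_clamped=n_clamped + state.n_clamped_po2 + state.n_clamped_pco2,
        grid=grid, velocity=velocity, bc=bc, settings=settings,
        closure=closure, params=params, constants=constants,
        outer_iterations=it, symmetry=symmetry, warnings=warnings,
    )


def graetz_reference(peclet: float, length: float, half_gap: float,
                     n_terms: int = 50) -> tuple[float, float]:
    """Mixed-cup decay of the plug-flow slit Graetz problem.

    For plug flow between Dirichlet walls separated by 2*half_gap (or a
    wall and a symmetry plane separated by half_gap), constant diffusivity
    D and negligible axial diffusion, the scaled mixed-cup excess
    ``theta = (P_mean - P_wall)/(P_in - P_wall)`` at axial position L is

        theta = sum_k (2/lam_k^2) * exp(-lam_k^2 * xi),
        lam_k = (2k-1) pi/2,   xi = L / (Pe * half_gap),

    with ``peclet = u * half_gap / D``.  Returns ``(theta, trunc)`` where
    ``trunc`` is the magnitude of the first neglected term.
    """
    if n_terms < 10:
        raise ParameterError("n_terms must be at least 10")
    if peclet <= 0 or half_gap <= 0:
        raise ParameterError("peclet and half_gap must be positive")
    xi = length / (peclet * half_gap)
    k = np.arange(1, n_terms + 2)
    lam = (2 * k - 1) * np.pi / 2.0
    terms = (2.0 / lam ** 2) * np.exp(-lam ** 2 * xi)
    return float(terms[:n_terms].sum()), float(terms[n_terms])
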