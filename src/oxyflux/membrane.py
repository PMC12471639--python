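"""Hollow-fiber membrane transport and blood rheology helpers.

Gas transport through the microporous polymethylpentene fiber wall is
Knudsen-dominated (pore diameters of a few hundred nm), so the wall is
characterised experimentally by a permeance Km (cm^3 STP / s / cm^2 / cmHg).
``membrane_diffusivity`` converts that permeance into an equivalent
effective diffusion coefficient for an explicitly meshed membrane region;
``wall_permeance`` goes the other way, collapsing the wall into a Robin
(series-resistance) boundary condition for a reduced blood-channel domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterError

__all__ = [
    "MembraneSpec",
    "RheologyParams",
    "membrane_diffusivity",
    "wall_permeance",
    "carreau_yasuda_viscosity",
    "fiber_pitch",
    "flow_descriptors",
]

CMHG_PER_MMHG = 0.1


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry and transport properties of the hollow-fiber wall.

    Defaults describe a PMP fiber: 380/200 um outer/inner diameter,
    permeances 1.08e-3 (O2) and 1.40e-3 (CO2) cm^3/s/cm^2/cmHg, tortuosity 4,
    effective porosity 0.5, pore diameter 249 nm, referenced to 298 K and
    760 mmHg.
    """

    d_outer: float = 380.0     # um
    d_inner: float = 200.0     # um
    Km_O2: float = 1.08e-3     # cm^3(STP)/s/cm^2/cmHg
    Km_CO2: float = 1.40e-3    # cm^3(STP)/s/cm^2/cmHg
    tau: float = 4.0           # tortuosity
    eps: float = 0.5           # effective porosity
    d_pore: float = 249.0      # nm
    T0: float = 298.0          # K, reference temperature
    P0: float = 760.0          # mmHg, reference pressure

    def __post_init__(self) -> None:
        if self.d_outer <= self.d_inner:
            raise ParameterError("d_outer must exceed d_inner")
        if not 0.0 < self.eps < 1.0:
            raise ParameterError(f"eps must lie in (0, 1), got {self.eps}")
        if self.tau < 1.0:
            raise ParameterError(f"tau must be >= 1, got {self.tau}")
        for name in ("Km_O2", "Km_CO2", "d_pore", "T0", "P0"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be strictly positive")

    @property
    def h(self) -> float:
        """Wall thickness, um."""
        return 0.5 * (self.d_outer - self.d_inner)

    def Km(self, gas: str) -> float:
        if gas.upper() == "O2":
            return self.Km_O2
        if gas.upper() == "CO2":
            return self.Km_CO2
        raise ParameterError(f"unknown gas {gas!r}")


@dataclass(frozen=True)
class RheologyParams:
    """Carreau-Yasuda shear-thinning blood rheology, SI units.

    mu(gdot) = mu_inf + (mu0 - mu_inf) * (1 + (lam*gdot)^a)^((n-1)/a)

    The defaults are standard literature whole-blood values (Carreau-Yasuda
    fit to steady-shear data; not device-specific).
    """

    rho: float = 1050.0     # kg/m^3
    mu0: float = 0.056      # Pa s, zero-shear viscosity
    mu_inf: float = 0.00345  # Pa s, infinite-shear viscosity
    lam: float = 3.313      # s, relaxation time
    a: float = 2.0          # Yasuda transition exponent
    n: float = 0.3568       # power-law index

    def __post_init__(self) -> None:
        if self.mu_inf >= self.mu0:
            raise ParameterError("mu_inf must be below mu0")
        if self.lam <= 0:
            raise ParameterError("lam must be positive")
        if self.rho <= 0:
            raise ParameterError("rho must be positive")


def membrane_diffusivity(gas: str, spec: MembraneSpec | None = None,
                         T: float = 310.0) -> float:
    """Knudsen-equivalent effective diffusivity of the fiber wall, m^2/s.

    Converts the measured permeance into the diffusion coefficient of an
    explicitly meshed membrane region:

        D = Km * (tau/eps) * h * (T/T0) * P0

    with Km in cm/s/cmHg, h in cm and P0 in cmHg (result cm^2/s -> m^2/s).
    The tau/eps factor undoes the porous-medium obstruction folded into the
    measured permeance; the grouping is fixed by requiring that a slab of
    thickness h with pore fraction eps/tau and this D reproduces exactly the
    measured permeance flux Km * dP at the reference state.
    """
    spec = spec or MembraneSpec()
    if T <= 0:
        raise ParameterError("temperature must be positive (K)")
    h_cm = spec.h * 1e-4
    p0_cmhg = spec.P0 * CMHG_PER_MMHG
    d_cm2 = spec.Km(gas) * (spec.tau / spec.eps) * h_cm * (T / spec.T0) * p0_cmhg
    return d_cm2 * 1e-4


def wall_permeance(spec: MembraneSpec | None = None, gas: str = "O2",
                   T: float = 310.0, diffusivity: float | None = None) -> float:
    """Wall permeance for the Robin boundary condition,
    mL gas (STP) / s / cm^2 / mmHg.

    Inverse of :func:`membrane_diffusivity`: a slab of thickness h, pore
    fraction eps/tau and diffusivity D passes an STP volume flux

        j = D * (eps/tau) * (T0/T) / (P0 * h) * dP.

    With the spec's own diffusivity this returns Km/10 (per mmHg) exactly;
    passing ``diffusivity`` explicitly lets the wall resistance be scaled
    independently (permeance ~ D/h, diverging in the thin-wall Dirichlet
    limit).
    """
    spec = spec or MembraneSpec()
    if diffusivity is None:
        diffusivity = membrane_diffusivity(gas, spec, T)
    d_cm2 = diffusivity * 1e4
    h_cm = spec.h * 1e-4
    p0_cmhg = spec.P0 * CMHG_PER_MMHG
    perm_per_cmhg = d_cm2 * (spec.eps / spec.tau) * (spec.T0 / T) / (p0_cmhg * h_cm)
    return perm_per_cmhg * CMHG_PER_MMHG


def carreau_yasuda_viscosity(shear_rate, params: RheologyParams | None = None):
    """Carreau-Yasuda apparent viscosity at the given shear rate (Pa s)."""
    params = params or RheologyParams()
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ParameterError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * gdot) ** params.a) ** ((params.n - 1.0) / params.a)
    return float(mu) if np.ndim(shear_rate) == 0 else mu


def fiber_pitch(linear_density: float) -> float:
    """Center-to-center fiber pitch (um) from a linear density in fibers/cm,
    rounded to one decimal (18 fibers/cm -> 555.6 um)."""
    if linear_density <= 0:
        raise ParameterError("linear density must be positive")
    return round(10_000.0 / linear_density, 1)


def flow_descriptors(Q: float, frontal_area: float, char_length: float,
                     rheology: RheologyParams | None = None,
                     viscosity: float | None = None) -> tuple[float, float]:
    """Superficial velocity (cm/s) and Reynolds number for a bundle.

    v = Q / (60 * A) with Q in mL/min and A in cm^2; Re = rho*v*L/mu with the
    caller-supplied representative viscosity (defaults to the infinite-shear
    Carreau-Yasuda value).
    """
    rheology = rheology or RheologyParams()
    if Q <= 0 or frontal_area <= 0 or char_length <= 0:
        raise ParameterError("Q, frontal_area and char_length must be positive")
    v_cm_s = Q / (60.0 * frontal_area)
    mu = rheology.mu_inf if viscosity is None else viscosity
    re = rheology.rho * (v_cm_s * 1e-2) * char_length / mu
    return v_cm_s, re
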