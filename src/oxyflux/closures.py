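"""Pluggable gas-carriage closures for the transport solver.

A closure supplies, for each species, three local functions of the pressure
fields:

* ``*_content(P...)`` — the convected total content (mL gas/mL blood);
* ``*_slope(P...)``   — its derivative with respect to the species' own
  partial pressure (the capacity, mL/mL/mmHg);
* ``*_flux_coeff(P...)`` — the diffusive content-flux coefficient
  Gamma = sum_i D_i * w_i (m^2/s * mL/mL/mmHg), whose ratio to the slope is
  the effective diffusivity of the one-field pressure equation.

Three closures are provided: the fully coupled Bohr/Haldane physiology, a
frozen (Hill-curve) O2 saturation closure in the style of fixed-curve
oxygenator models, and a constant-slope CO2 content closure in the style of
the classical constant-content-curve CO2 models.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import physiology as phys
from .parameters import BloodParameters, GasTransportConstants

__all__ = [
    "Closure",
    "CoupledClosure",
    "FrozenO2CurveClosure",
    "ConstantCO2SlopeClosure",
    "LinearTracerClosure",
    "fit_hill_to_kelman",
    "make_closure",
]


class Closure:
    """Base closure: fully coupled physiology for both species."""

    tag = "coupled"

    def __init__(self, params: BloodParameters | None = None,
                 constants: GasTransportConstants | None = None,
                 co2_mode: str = "buffer_line"):
        self.params = params or BloodParameters()
        self.constants = constants or GasTransportConstants()
        self.co2_mode = co2_mode

    # -- O2 ---------------------------------------------------------------
    def o2_slope(self, po2, pco2):
        c = self.constants
        return c.alpha_O2 + c.k_O2 * self.params.Hb * np.asarray(
            phys.dso2_dpo2(po2, pco2, self.params, c))

    def o2_flux_coeff(self, po2, pco2):
        c = self.constants
        w2 = c.k_O2 * self.params.Hb * np.asarray(
            phys.dso2_dpo2(po2, pco2, self.params, c))
        return c.D_O2 * c.alpha_O2 + c.D_HbO2 * w2

    def o2_content(self, po2, pco2):
        return np.asarray(phys.o2_content(po2, pco2, self.params, self.constants))

    def deff_o2(self, po2, pco2):
        return self.o2_flux_coeff(po2, pco2) / self.o2_slope(po2, pco2)

    # -- CO2 --------------------------------------------------------------
    def _co2_weights(self, pco2, po2):
        c = self.constants
        w1 = c.alpha_CO2_ml
        w2 = c.k_CO2 * self.params.Hb * np.asarray(
            phys.dsco2_dpco2(pco2, po2, self.params, c, mode=self.co2_mode))
        w3 = np.asarray(phys.dchco3_dpco2(pco2, self.params))
        return w1, w2, w3

    def co2_slope(self, pco2, po2):
        w1, w2, w3 = self._co2_weights(pco2, po2)
        return w1 + w2 + w3

    def co2_flux_coeff(self, pco2, po2):
        c = self.constants
        w1, w2, w3 = self._co2_weights(pco2, po2)
        return c.D_CO2 * w1 + c.D_HbCO2 * w2 + c.D_HCO3 * w3

    def co2_content(self, pco2, po2):
        """Three-pool convected CO2 content (dissolved + carbamino +
        bicarbonate); its PCO2-derivative along the buffer line equals
        ``co2_slope`` exactly, which makes the wall-flux / mixed-cup
        conservation identity hold at the discrete level."""
        p = self.params
        c = self.constants
        po2c, pco2c, _, _ = phys.clamp_pressures(po2, pco2, p)
        ab = phys.solve_acid_base(pco2c, p)
        s = phys.sco2(pco2c, po2c, ab.pH, p.T, c, p)
        return (c.alpha_CO2_ml * pco2c + c.k_CO2 * p.Hb * np.asarray(s)
                + np.asarray(ab.C_HCO3_ml))

    def deff_co2(self, pco2, po2):
        return self.co2_flux_coeff(pco2, po2) / self.co2_slope(pco2, po2)

    # -- fused evaluations used by the solver inner loop ------------------
    # One acid-base solve feeds flux coefficient, capacity and content
    # simultaneously; subclasses with cheaper species models override.

    def o2_fields(self, po2, pco2):
        """Return (flux_coeff, slope, content) for O2 in one pass."""
        p, c = self.params, self.constants
        po2c, pco2c, _, _ = phys.clamp_pressures(po2, pco2, p)
        ph = phys.solve_acid_base(pco2c, p).pH
        bohr = phys.adjusted_po2(1.0, p.T, np.asarray(ph), pco2c)
        x = bohr * po2c
        sat = phys.kelman_saturation(x, c)
        sprime = phys.kelman_slope(x, c) * bohr
        w2 = c.k_O2 * p.Hb * np.asarray(sprime)
        gamma = c.D_O2 * c.alpha_O2 + c.D_HbO2 * w2
        slope = c.alpha_O2 + w2
        content = c.alpha_O2 * po2c + c.k_O2 * p.Hb * np.asarray(sat)
        return gamma, slope, content

    def co2_fields(self, pco2, po2):
        """Return (flux_coeff, slope, content) for CO2 in one pass."""
        p, c = self.params, self.constants
        po2c, pco2c, _, _ = phys.clamp_pressures(po2, pco2, p)
        ab = phys.solve_acid_base(pco2c, p)
        ph = np.asarray(ab.pH)
        phprime = -(1.0 / (pco2c * phys.LN10)) / (
            1.0 + ab.beta_NC / (np.asarray(ab.C_HCO3_mmol) * phys.LN10))
        hal = phys.adjusted_pco2(1.0, p.T, ph, po2c)
        x = hal * pco2c
        sat = phys.hill_sco2(x, c)
        hslope = phys.hill_slope(x, c)
        if self.co2_mode == "buffer_line":
            _, cph, _ = phys.HALDANE_COEFFS
            dx_dp = hal * (1.0 + pco2c * phys.LN10 * cph * phprime)
        else:
            dx_dp = hal
        w2 = c.k_CO2 * p.Hb * hslope * dx_dp
        w3 = -ab.beta_NC * phprime * p.unit_conv
        gamma = c.D_CO2 * c.alpha_CO2_ml + c.D_HbCO2 * w2 + c.D_HCO3 * w3
        slope = c.alpha_CO2_ml + w2 + w3
        content = (c.alpha_CO2_ml * pco2c + c.k_CO2 * p.Hb * np.asarray(sat)
                   + np.asarray(ab.C_HCO3_ml))
        return gamma, slope, content


CoupledClosure = Closure


class FrozenO2CurveClosure(Closure):
    """Fixed Hill-curve O2 saturation (no Bohr coupling); CO2 side coupled.

    ``p50`` and ``n`` default to a two-point match of the Kelman curve at
    standard conditions (T 37 C, pH 7.4, PCO2 40 mmHg): exact at 50%
    saturation and at a second reference pressure.
    """

    tag = "frozen_o2_curve"

    def __init__(self, params=None, constants=None, co2_mode="buffer_line",
                 p50: float | None = None, n: float | None = None,
                 match_point: float = 60.0):
        super().__init__(params, constants, co2_mode)
        if p50 is None or n is None:
            p50_fit, n_fit = fit_hill_to_kelman(self.constants, match_point)
            p50 = p50 if p50 is not None else p50_fit
            n = n if n is not None else n_fit
        self.p50 = float(p50)
        self.n = float(n)

    def _hill(self, po2):
        y = np.maximum(np.asarray(po2, float), 0.0) / self.p50
        yn = np.where(y > 0, y, 1.0) ** self.n
        yn = np.where(np.asarray(y) > 0, yn, 0.0)
        return yn / (1.0 + yn)

    def _hill_slope(self, po2):
        p = np.maximum(np.asarray(po2, float), 1e-12)
        y = p / self.p50
        yn = y ** self.n
        return self.n * yn / (p * (1.0 + yn) ** 2)

    def o2_saturation(self, po2, pco2=None):
        return self._hill(po2)

    def o2_slope(self, po2, pco2):
        c = self.constants
        return c.alpha_O2 + c.k_O2 * self.params.Hb * self._hill_slope(po2)

    def o2_flux_coeff(self, po2, pco2):
        c = self.constants
        w2 = c.k_O2 * self.params.Hb * self._hill_slope(po2)
        return c.D_O2 * c.alpha_O2 + c.D_HbO2 * w2

    def o2_content(self, po2, pco2):
        c = self.constants
        return c.alpha_O2 * np.asarray(po2, float) \
            + c.k_O2 * self.params.Hb * self._hill(po2)

    def o2_fields(self, po2, pco2):
        return (self.o2_flux_coeff(po2, pco2), self.o2_slope(po2, pco2),
                self.o2_content(po2, pco2))


def fit_hill_to_kelman(constants: GasTransportConstants,
                       match_point: float = 60.0) -> tuple[float, float]:
    """Fit a Hill curve to the Kelman curve at standard conditions.

    P50 solves Kelman(P50) = 0.5; the exponent makes the Hill curve exact
    at ``match_point`` as well (log-odds match).
    """
    p50 = brentq(lambda p: phys.kelman_saturation(p, constants) - 0.5,
                 5.0, 100.0, xtol=1e-12)
    s2 = phys.kelman_saturation(match_point, constants)
    n = np.log(s2 / (1.0 - s2)) / np.log(match_point / p50)
    return float(p50), float(n)


class ConstantCO2SlopeClosure(Closure):
    """Constant-slope CO2 content curve (chord over a reference PCO2 window);
    O2 side coupled.

    The total CO2 content is linearised about the window midpoint with the
    chord slope of the coupled content curve over ``pco2_window`` (evaluated
    at ``po2_ref`` along the buffer line), and the diffusive flux
    coefficient is frozen at its window-average, so the effective CO2
    diffusivity is independent of the local PCO2.
    """

    tag = "constant_co2_slope"

    def __init__(self, params=None, constants=None, co2_mode="buffer_line",
                 pco2_window: tuple[float, float] = (25.0, 50.0),
                 po2_ref: float = 35.9):
        super().__init__(params, constants, co2_mode)
        lo, hi = pco2_window
        if not hi > lo > 0:
            raise ValueError("pco2_window must be an increasing positive pair")
        self.pco2_window = (float(lo), float(hi))
        self.po2_ref = float(po2_ref)
        mid = 0.5 * (lo + hi)
        c_lo = float(np.asarray(super().co2_content(lo, po2_ref)))
        c_hi = float(np.asarray(super().co2_content(hi, po2_ref)))
        self._slope = (c_hi - c_lo) / (hi - lo)
        self._c_mid = float(np.asarray(super().co2_content(mid, po2_ref)))
        self._p_mid = mid
        pgrid = np.linspace(lo, hi, 11)
        self._gamma = float(np.mean(np.asarray(
            super().co2_flux_coeff(pgrid, np.full_like(pgrid, po2_ref)))))

    def co2_slope(self, pco2, po2):
        return np.full(np.broadcast(np.asarray(pco2), np.asarray(po2)).shape
                       or (), self._slope)

    def co2_flux_coeff(self, pco2, po2):
        return np.full(np.broadcast(np.asarray(pco2), np.asarray(po2)).shape
                       or (), self._gamma)

    def co2_content(self, pco2, po2):
        return self._c_mid + self._slope * (np.asarray(pco2, float) - self._p_mid)

    def co2_fields(self, pco2, po2):
        return (self.co2_flux_coeff(pco2, po2), self.co2_slope(pco2, po2),
                self.co2_content(pco2, po2))


class LinearTracerClosure(Closure):
    """Constant-property linear closure (content = capacity * pressure).

    Used for verification against closed-form transport solutions (pure
    diffusion, the Graetz problem), where both species behave as passive
    tracers with prescribed constant diffusivities.
    """

    tag = "linear_tracer"

    def __init__(self, params=None, constants=None, D_o2: float = 1e-9,
                 D_co2: float = 1e-9, capacity: float = 1.0):
        super().__init__(params, constants)
        self.D_o2 = float(D_o2)
        self.D_co2 = float(D_co2)
        self.capacity = float(capacity)

    def _const(self, p, val):
        return np.full(np.asarray(p, float).shape or (), val)

    def o2_slope(self, po2, pco2):
        return self._const(po2, self.capacity)

    def o2_flux_coeff(self, po2, pco2):
        return self._const(po2, self.D_o2 * self.capacity)

    def o2_content(self, po2, pco2):
        return self.capacity * np.asarray(po2, float)

    def co2_slope(self, pco2, po2):
        return self._const(pco2, self.capacity)

    def co2_flux_coeff(self, pco2, po2):
        return self._const(pco2, self.D_co2 * self.capacity)

    def co2_content(self, pco2, po2):
        return self.capacity * np.asarray(pco2, float)

    def o2_fields(self, po2, pco2):
        return (self.o2_flux_coeff(po2, pco2), self.o2_slope(po2, pco2),
                self.o2_content(po2, pco2))

    def co2_fields(self, pco2, po2):
        return (self.co2_flux_coeff(pco2, po2), self.co2_slope(pco2, po2),
                self.co2_content(pco2, po2))


_CLOSURES = {
    "coupled": CoupledClosure,
    "frozen_o2_curve": FrozenO2CurveClosure,
    "constant_co2_slope": ConstantCO2SlopeClosure,
    "linear_tracer": LinearTracerClosure,
}


def make_closure(name: str, params=None, constants=None, **kwargs) -> Closure:
    """Instantiate a closure by its configuration id."""
    try:
        cls = _CLOSURES[name]
    except KeyError:
        raise ValueError(
            f"unknown closure {name!r}; choose from {sorted(_CLOSURES)}") from None
    return cls(params=params, constants=constants, **kwargs)
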