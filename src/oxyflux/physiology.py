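"""Pointwise blood-gas physiology.

This module couples four classical submodels into a single differentiable
description of whole-blood gas carriage:

* the Henderson-Hasselbalch relation together with the Van Slyke buffer line,
  solved simultaneously for plasma pH and bicarbonate at a given PCO2;
* the Kelman quartic-rational oxyhemoglobin dissociation curve, with the
  Bohr-effect pressure adjustment (temperature, pH, PCO2);
* a Hill-form carbamino CO2 saturation curve with a Haldane-effect pressure
  adjustment (temperature, pH, PO2);
* the McHardy total CO2 content correction, which reduces CO2 carriage as
  oxygen saturation rises (Haldane direction).

From these it derives the analytic slopes (dSO2/dPO2, dSCO2/dPCO2,
dCHCO3/dPCO2) and the effective diffusivities used by the one-field
advection-diffusion transport equations: each effective diffusivity is the
capacity-weighted mean of the free and carrier-bound diffusivities, the
weights being the local slopes of the respective content pools.

All functions accept scalars or numpy arrays and broadcast; pressures are in
mmHg, contents in mL gas (STP) / mL blood, diffusivities in m^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import BloodParameters, GasTransportConstants, ParameterError

__all__ = [
    "AcidBaseState",
    "LocalGasState",
    "AcidBaseError",
    "buffer_power",
    "solve_acid_base",
    "dph_dpco2",
    "adjusted_po2",
    "kelman_saturation",
    "kelman_slope",
    "so2",
    "adjusted_pco2",
    "hill_sco2",
    "hill_slope",
    "sco2",
    "dso2_dpo2",
    "dsco2_dpco2",
    "dchco3_dpco2",
    "o2_content",
    "co2_content",
    "deff_o2",
    "deff_co2",
    "source_terms",
    "evaluate_state",
    "clamp_pressures",
]

LN10 = np.log(10.0)

#: Henry-law CO2 solubility entering the Henderson-Hasselbalch relation,
#: mmol / L blood / mmHg.
_ALPHA_CO2 = 0.0307

#: Bohr-adjustment coefficients (temperature, pH, log-PCO2 terms) of the
#: adjusted oxygen pressure.
BOHR_COEFFS = (0.024, 0.40, 0.06)
#: Haldane-adjustment coefficients (temperature, pH, log-PO2 terms) of the
#: adjusted carbon dioxide pressure.
HALDANE_COEFFS = (0.004, 1.66, 0.02)


class AcidBaseError(RuntimeError):
    """Raised when the acid-base Newton iteration fails to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class AcidBaseState:
    """Simultaneous solution of the Henderson-Hasselbalch / Van Slyke system.

    ``pH`` and ``C_HCO3_mmol`` satisfy both the Henderson-Hasselbalch
    relation (at the configured pKa and CO2 solubility) and the buffer line
    ``C_HCO3 = 24.4 + BE - beta_NC*(pH - 7.4)`` to within ``residual``.
    Fields may be scalars or arrays, matching the PCO2 input.
    """

    pH: np.ndarray | float
    C_HCO3_mmol: np.ndarray | float
    C_HCO3_ml: np.ndarray | float
    beta_NC: float
    residual: np.ndarray | float


@dataclass(frozen=True)
class LocalGasState:
    """Complete pointwise gas state at (PO2, PCO2): saturations, contents,
    slopes and effective diffusivities, plus clamp-event counts."""

    PO2: np.ndarray | float
    PCO2: np.ndarray | float
    PO2_adj: np.ndarray | float
    PCO2_adj: np.ndarray | float
    pH: np.ndarray | float
    SO2: np.ndarray | float
    SCO2: np.ndarray | float
    C_O2: np.ndarray | float
    C_CO2: np.ndarray | float
    C_HCO3_ml: np.ndarray | float
    dSO2_dPO2: np.ndarray | float
    dSCO2_dPCO2: np.ndarray | float
    dCHCO3_dPCO2: np.ndarray | float
    Deff_O2: np.ndarray | float
    Deff_CO2: np.ndarray | float
    n_clamped_po2: int
    n_clamped_pco2: int


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x) if scalar else x


def clamp_pressures(po2, pco2, params: BloodParameters):
    """Clamp (PO2, PCO2) into the admissible evaluation box.

    Returns ``(po2_clamped, pco2_clamped, n_po2_events, n_pco2_events)``.
    The clamp exists because the wall boundary conditions (PCO2 = 0 at the
    CO2-stripping wall) sit exactly on the singularities of the logarithmic
    Bohr term and the Henderson-Hasselbalch relation.
    """
    po2 = np.asarray(po2, dtype=float)
    pco2 = np.asarray(pco2, dtype=float)
    n_po2 = int(np.count_nonzero((po2 < params.po2_floor) | (po2 > params.po2_ceil)))
    n_pco2 = int(np.count_nonzero((pco2 < params.pco2_floor) | (pco2 > params.pco2_ceil)))
    return (
        np.clip(po2, params.po2_floor, params.po2_ceil),
        np.clip(pco2, params.pco2_floor, params.pco2_ceil),
        n_po2,
        n_pco2,
    )


# ---------------------------------------------------------------------------
# Acid-base system
# ---------------------------------------------------------------------------

def buffer_power(Hb: float) -> float:
    """Non-carbonic buffer power beta_NC (mmol/L per pH unit).

    Linear in hemoglobin (entered in g/mL, converted internally to g/dL);
    the intercept 7.7 is the plasma-protein contribution.
    """
    if Hb < 0:
        raise ParameterError(f"Hb must be non-negative, got {Hb}")
    return 1.43 * (Hb * 100.0) + 7.7


def _buffer_line(ph, params: BloodParameters, beta: float):
    """Bicarbonate on the Van Slyke buffer line, mmol/L."""
    return 24.4 + params.BE - beta * (ph - 7.4)


def solve_acid_base(pco2, params: BloodParameters | None = None,
                    tol: float = 1e-10, max_iter: int = 50) -> AcidBaseState:
    """Solve the coupled Henderson-Hasselbalch / Van Slyke system for pH.

    Substituting the buffer line into the Henderson-Hasselbalch relation
    gives a scalar residual in pH,

        f(pH) = pH - pKa - log10( C_HCO3(pH) / (alpha_CO2 * PCO2) ),

    which is smooth and strictly increasing on the physical branch
    (C_HCO3 > 0).  Newton-Raphson from pH = 7.4 with the analytic
    derivative converges in a handful of iterations; any element that
    strays outside the physical bracket falls back to bracketed root
    finding on (5.5, pH_max), where pH_max is the zero-bicarbonate
    asymptote of the buffer line.
    """
    params = params or BloodParameters()
    pco2_arr = np.asarray(pco2, dtype=float)
    scalar = pco2_arr.ndim == 0
    shape = pco2_arr.shape
    p = np.atleast_1d(np.clip(pco2_arr, params.pco2_floor, params.pco2_ceil)).ravel()

    beta = buffer_power(params.Hb)
    ph_max = 7.4 + (24.4 + params.BE) / beta  # C_HCO3 -> 0 here
    log_ap = np.log10(_ALPHA_CO2 * p)

    ph = np.full_like(p, 7.4)
    converged = np.zeros(p.shape, dtype=bool)
    res = np.full_like(p, np.inf)
    for _ in range(max_iter):
        c = _buffer_line(ph, params, beta)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = ph - params.pKa - np.log10(c) + log_ap
            fp = 1.0 + beta / (c * LN10)
        res = np.abs(f)
        converged = res <= tol
        if converged.all():
            break
        step = np.where(converged, 0.0, f / fp)
        ph = ph - step
        # keep iterates strictly inside the physical branch
        bad = ~np.isfinite(ph) | (ph >= ph_max) | (ph <= 5.5)
        ph = np.where(bad, np.nan, ph)
        if np.isnan(ph).any():
            break

    if not converged.all():
        idx = np.nonzero(~converged.ravel())[0]
        for i in idx:
            def f_scalar(x, pi=p[i]):
                return x - params.pKa - np.log10(_buffer_line(x, params, beta)
                                                / (_ALPHA_CO2 * pi))
            try:
                ph[i] = brentq(f_scalar, 5.5, ph_max - 1e-12, xtol=1e-14, rtol=8.9e-16)
            except ValueError as exc:  # no sign change: unphysical input
                raise AcidBaseError(
                    f"acid-base solve failed at PCO2={p[i]:g} mmHg", float(res[i])
                ) from exc
            res[i] = abs(f_scalar(ph[i]))
        if (res > 1e-9).any():
            raise AcidBaseError("acid-base residual above tolerance",
                                float(res.max()))

    c = _buffer_line(ph, params, beta)
    if scalar:
        return AcidBaseState(pH=float(ph[0]), C_HCO3_mmol=float(c[0]),
                             C_HCO3_ml=float(params.unit_conv * c[0]),
                             beta_NC=beta, residual=float(res[0]))
    return AcidBaseState(pH=ph.reshape(shape), C_HCO3_mmol=c.reshape(shape),
                         C_HCO3_ml=(params.unit_conv * c).reshape(shape),
                         beta_NC=beta, residual=res.reshape(shape))


def dph_dpco2(pco2, params: BloodParameters | None = None):
    """Analytic slope of the equilibrium pH with respect to PCO2.

    Implicit differentiation of the combined acid-base system:
    ``dpH/dPCO2 = -(1/(PCO2 ln10)) / (1 + beta_NC/(C_HCO3 ln10))``.
    Strictly negative: CO2 loading acidifies.
    """
    params = params or BloodParameters()
    state = solve_acid_base(pco2, params)
    p = np.clip(np.asarray(pco2, dtype=float), params.pco2_floor, params.pco2_ceil)
    denom = 1.0 + state.beta_NC / (np.asarray(state.C_HCO3_mmol) * LN10)
    out = -(1.0 / (p * LN10)) / denom
    return float(out) if np.ndim(pco2) == 0 else out


# ---------------------------------------------------------------------------
# Oxygen side: Bohr adjustment + Kelman curve
# ---------------------------------------------------------------------------

def adjusted_po2(po2, T, ph, pco2, coeffs=BOHR_COEFFS):
    """Bohr-adjusted oxygen partial pressure.

    ``PO2_adj = PO2 * 10**(cT*(37-T) + cpH*(pH-7.4) + clog*log10(40/PCO2))``.
    Equals PO2 exactly at T = 37 C, pH = 7.4, PCO2 = 40 mmHg.  The caller is
    responsible for clamping PCO2 away from zero.
    """
    cT, cph, clog = coeffs
    expo = cT * (37.0 - np.asarray(T, float)) + cph * (np.asarray(ph, float) - 7.4) \
        + clog * np.log10(40.0 / np.asarray(pco2, float))
    return po2 * 10.0 ** expo


def _kelman_polys(x, coeffs):
    a1, a2, a3, a4, a5, a6, a7 = coeffs
    num = x * (a1 + x * (a2 + x * (a3 + x)))
    den = a4 + x * (a5 + x * (a6 + x * (a7 + x)))
    dnum = a1 + x * (2 * a2 + x * (3 * a3 + 4 * x))
    dden = a5 + x * (2 * a6 + x * (3 * a7 + 4 * x))
    return num, den, dnum, dden


def kelman_saturation(po2_adj, constants: GasTransportConstants | None = None):
    """Kelman quartic-rational oxyhemoglobin saturation, clamped to [0, 1].

    The leading numerator coefficient is negative, so the raw rational dips
    slightly below zero for adjusted pressures under ~4 mmHg; clamping
    restores saturation semantics there.
    """
    constants = constants or GasTransportConstants()
    x = np.asarray(po2_adj, dtype=float)
    num, den, _, _ = _kelman_polys(x, constants.kelman)
    s = np.clip(num / den, 0.0, 1.0)
    return float(s) if np.ndim(po2_adj) == 0 else s


def kelman_slope(po2_adj, constants: GasTransportConstants | None = None):
    """Derivative of the Kelman curve with respect to adjusted PO2 (1/mmHg).

    Zero wherever the raw rational is outside [0, 1] (the clamped region).
    """
    constants = constants or GasTransportConstants()
    x = np.asarray(po2_adj, dtype=float)
    num, den, dnum, dden = _kelman_polys(x, constants.kelman)
    raw = num / den
    slope = (dnum * den - num * dden) / den ** 2
    slope = np.where((raw < 0.0) | (raw > 1.0), 0.0, slope)
    return float(slope) if np.ndim(po2_adj) == 0 else slope


def so2(po2, pco2, params: BloodParameters | None = None,
        constants: GasTransportConstants | None = None,
        bohr_coeffs=BOHR_COEFFS):
    """Bohr-coupled oxygen saturation at (PO2, PCO2).

    Plasma pH is obtained from the acid-base system at the local PCO2, the
    Bohr adjustment rescales PO2, and the Kelman curve maps the adjusted
    pressure to saturation.  Monotone increasing in PO2 and decreasing in
    PCO2 (both the pH and the log terms act in the Bohr direction).
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    po2c, pco2c, _, _ = clamp_pressures(po2, pco2, params)
    ph = solve_acid_base(pco2c, params).pH
    padj = adjusted_po2(po2c, params.T, ph, pco2c, bohr_coeffs)
    s = kelman_saturation(padj, constants)
    return float(np.asarray(s)) if np.ndim(po2) == 0 and np.ndim(pco2) == 0 else s


def dso2_dpo2(po2, pco2, params: BloodParameters | None = None,
              constants: GasTransportConstants | None = None):
    """Analytic slope dSO2/dPO2 at fixed PCO2 (1/mmHg).

    The Bohr factor is independent of PO2, so with ``PO2_adj = c * PO2`` the
    chain rule gives ``dS/dPO2 = S'(PO2_adj) * c``.
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    po2c, pco2c, _, _ = clamp_pressures(po2, pco2, params)
    ph = solve_acid_base(pco2c, params).pH
    c = adjusted_po2(1.0, params.T, ph, pco2c)
    out = kelman_slope(c * po2c, constants) * c
    return float(np.asarray(out)) if np.ndim(po2) == 0 and np.ndim(pco2) == 0 else out


# ---------------------------------------------------------------------------
# Carbon dioxide side: Haldane adjustment + Hill curve
# ---------------------------------------------------------------------------

def adjusted_pco2(pco2, T, ph, po2, coeffs=HALDANE_COEFFS):
    """Haldane-adjusted carbon dioxide partial pressure.

    ``PCO2_adj = PCO2 * 10**(cT*(37-T) + cpH*(pH-7.4) + clog*log10(100/PO2))``.
    Identity at T = 37 C, pH = 7.4, PO2 = 100 mmHg.
    """
    cT, cph, clog = coeffs
    expo = cT * (37.0 - np.asarray(T, float)) + cph * (np.asarray(ph, float) - 7.4) \
        + clog * np.log10(100.0 / np.asarray(po2, float))
    return pco2 * 10.0 ** expo


def hill_sco2(pco2_adj, constants: GasTransportConstants | None = None):
    """Hill-form CO2 saturation of hemoglobin, S = y^n/(1+y^n), y = P/P50."""
    constants = constants or GasTransportConstants()
    y = np.asarray(pco2_adj, dtype=float) / constants.P50_CO2
    with np.errstate(divide="ignore"):
        yn = np.where(y > 0, y, np.nan) ** constants.n_CO2
    yn = np.where(np.asarray(y) <= 0, 0.0, yn)
    s = yn / (1.0 + yn)
    return float(s) if np.ndim(pco2_adj) == 0 else s


def hill_slope(pco2_adj, constants: GasTransportConstants | None = None):
    """Derivative of the Hill CO2 curve with respect to adjusted PCO2."""
    constants = constants or GasTransportConstants()
    n, p50 = constants.n_CO2, constants.P50_CO2
    y = np.asarray(pco2_adj, dtype=float) / p50
    with np.errstate(divide="ignore", invalid="ignore"):
        yn = np.where(y > 0, y, np.nan) ** n
        out = n * yn / (np.asarray(pco2_adj) * (1.0 + yn) ** 2)
    out = np.where(np.asarray(y) <= 0, np.inf, out)  # n < 1: infinite slope at 0
    return float(out) if np.ndim(pco2_adj) == 0 else out


def sco2(pco2, po2, ph=7.4, T=37.0,
         constants: GasTransportConstants | None = None,
         params: BloodParameters | None = None,
         haldane_coeffs=HALDANE_COEFFS):
    """Haldane-coupled CO2 saturation at (PCO2, PO2, pH, T).

    pH enters explicitly (it is a function of PCO2 along the buffer line;
    passing it frozen gives the partial dependence).  Monotone increasing in
    PCO2 at fixed pH and decreasing in PO2 (Haldane direction).
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    po2c, pco2c, _, _ = clamp_pressures(po2, pco2, params)
    padj = adjusted_pco2(pco2c, T, ph, po2c, haldane_coeffs)
    s = hill_sco2(padj, constants)
    return float(np.asarray(s)) if np.ndim(pco2) == 0 and np.ndim(po2) == 0 else s


def dsco2_dpco2(pco2, po2, params: BloodParameters | None = None,
                constants: GasTransportConstants | None = None,
                mode: str = "buffer_line"):
    """Slope of the CO2 saturation with respect to PCO2 (1/mmHg).

    mode='frozen_pH'
        Partial derivative at fixed pH (taken from the acid-base system at
        the local PCO2 but not differentiated): the bare Hill-curve slope
        scaled by the Haldane factor.  Strictly positive.
    mode='buffer_line' (default)
        Total derivative with pH following PCO2 through the acid-base
        system.  Acidification right-shifts the CO2 curve (the 1.66 pH
        coefficient), which over most of the physiological range more than
        offsets the direct pressure rise, so this slope can be negative:
        carbamino carriage genuinely falls as CO2 loads along the buffer
        line.
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    po2c, pco2c, _, _ = clamp_pressures(po2, pco2, params)
    ph = solve_acid_base(pco2c, params).pH
    c = adjusted_pco2(1.0, params.T, ph, po2c)  # Haldane factor
    x = c * pco2c
    sprime = hill_slope(x, constants)
    if mode == "frozen_pH":
        out = sprime * c
    elif mode == "buffer_line":
        phprime = dph_dpco2(pco2c, params)
        _, cph, _ = HALDANE_COEFFS
        dx_dp = c * (1.0 + pco2c * LN10 * cph * np.asarray(phprime))
        out = sprime * dx_dp
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scalar = np.ndim(pco2) == 0 and np.ndim(po2) == 0
    return float(np.asarray(out)) if scalar else out


def dchco3_dpco2(pco2, params: BloodParameters | None = None):
    """Slope of bicarbonate content with respect to PCO2, mL CO2/mL blood/mmHg.

    Implicit differentiation of the acid-base system: on the buffer line
    ``dC/dpH = -beta_NC``, so ``dC/dPCO2 = -beta_NC * dpH/dPCO2 > 0``.
    """
    params = params or BloodParameters()
    beta = buffer_power(params.Hb)
    out = -beta * np.asarray(dph_dpco2(pco2, params)) * params.unit_conv
    return float(out) if np.ndim(pco2) == 0 else out


# ---------------------------------------------------------------------------
# Contents
# ---------------------------------------------------------------------------

def o2_content(po2, pco2, params: BloodParameters | None = None,
               constants: GasTransportConstants | None = None):
    """Total O2 content: dissolved plus hemoglobin-bound, mL O2/mL blood."""
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    s = so2(po2, pco2, params, constants)
    po2c, _, _, _ = clamp_pressures(po2, pco2, params)
    out = constants.alpha_O2 * po2c + constants.k_O2 * params.Hb * s
    scalar = np.ndim(po2) == 0 and np.ndim(pco2) == 0
    return float(np.asarray(out)) if scalar else out


def co2_content(pco2, po2, params: BloodParameters | None = None,
                constants: GasTransportConstants | None = None,
                variant: str = "kelman_grouping",
                include_dissolved: bool = False):
    """Total CO2 content by the McHardy correction, mL CO2/mL blood.

    ``C_CO2 = C_HCO3 * [1 - coef*Hb / ((2.244 - 0.422*SO2)(8.74 - pH))]``

    The bracketed factor reduces carriage as oxygen saturation rises (the
    Haldane direction) and as pH falls.  Two coefficient/unit conventions
    of the same formula circulate:

    * ``variant='kelman_grouping'`` (default): coefficient 0.02924 with Hb
      in g/dL, the grouping of the original whole-blood correction;
    * ``variant='as_printed'``: coefficient 0.2924 with Hb in g/mL, which
      yields a correction ten times weaker.

    Dissolved CO2 (alpha_CO2 * PCO2) is excluded by default, matching the
    bicarbonate-based formula; ``include_dissolved=True`` adds it.
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    po2c, pco2c, _, _ = clamp_pressures(po2, pco2, params)
    ab = solve_acid_base(pco2c, params)
    ph = np.asarray(ab.pH)
    if np.any(ph >= 8.74):
        raise ParameterError("McHardy correction undefined for pH >= 8.74")
    s = so2(po2c, pco2c, params, constants)
    if variant == "kelman_grouping":
        corr = 0.02924 * (params.Hb * 100.0)
    elif variant == "as_printed":
        corr = 0.2924 * params.Hb
    else:
        raise ValueError(f"unknown variant {variant!r}")
    out = np.asarray(ab.C_HCO3_ml) * (
        1.0 - corr / ((2.244 - 0.422 * np.asarray(s)) * (8.74 - ph)))
    if include_dissolved:
        out = out + constants.alpha_CO2_ml * pco2c
    scalar = np.ndim(po2) == 0 and np.ndim(pco2) == 0
    return float(np.asarray(out)) if scalar else out


# ---------------------------------------------------------------------------
# Effective diffusivities and source terms
# ---------------------------------------------------------------------------

def deff_o2(po2, pco2, params: BloodParameters | None = None,
            constants: GasTransportConstants | None = None,
            return_weights: bool = False):
    """Effective O2 diffusivity: capacity-weighted mean of the dissolved and
    oxyhemoglobin diffusivities.

    ``Deff = (D_O2*alpha_O2 + D_HbO2*k_O2*Hb*dSO2/dPO2)
             / (alpha_O2 + k_O2*Hb*dSO2/dPO2)``

    A convex combination of D_O2 and D_HbO2; it collapses to D_O2 on the
    saturation plateau where the dissociation slope vanishes.
    With ``return_weights=True`` also returns ``(w_dissolved, w_bound)`` —
    the numerator is the content-flux coefficient ``sum(w_i * D_i)`` and the
    denominator ``sum(w_i)`` is the total content slope.
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    w1 = constants.alpha_O2
    w2 = constants.k_O2 * params.Hb * np.asarray(dso2_dpo2(po2, pco2, params, constants))
    deff = (constants.D_O2 * w1 + constants.D_HbO2 * w2) / (w1 + w2)
    scalar = np.ndim(po2) == 0 and np.ndim(pco2) == 0
    deff = float(np.asarray(deff)) if scalar else deff
    if return_weights:
        return deff, (w1, float(w2) if scalar else w2)
    return deff


def deff_co2(pco2, po2, params: BloodParameters | None = None,
             constants: GasTransportConstants | None = None,
             mode: str = "buffer_line", return_weights: bool = False):
    """Effective CO2 diffusivity: three-way capacity-weighted mean over the
    dissolved, carbamino and bicarbonate pools.

    All three weights are content slopes in mL CO2/mL blood/mmHg (the molar
    CO2 solubility is converted with the 0.02226 factor).  The bicarbonate
    weight dominates in venous blood, pulling Deff toward D_HCO3.
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    w1 = constants.alpha_CO2_ml
    w2 = constants.k_CO2 * params.Hb * np.asarray(
        dsco2_dpco2(pco2, po2, params, constants, mode=mode))
    w3 = np.asarray(dchco3_dpco2(pco2, params))
    deff = ((constants.D_CO2 * w1 + constants.D_HbCO2 * w2
             + constants.D_HCO3 * w3) / (w1 + w2 + w3))
    scalar = np.ndim(pco2) == 0 and np.ndim(po2) == 0
    deff = float(np.asarray(deff)) if scalar else deff
    if return_weights:
        if scalar:
            return deff, (w1, float(w2), float(w3))
        return deff, (w1, w2, w3)
    return deff


def source_terms(po2, pco2, params: BloodParameters | None = None,
                 constants: GasTransportConstants | None = None,
                 mode: str = "paper", grad_po2_sq=0.0, grad_pco2_sq=0.0,
                 h: float = 1e-3):
    """Reaction-like source terms of the pressure-form transport equations.

    In the model as formulated the curvature-driven sources are neglected
    (``mode='paper'`` returns (0, 0)).  ``mode='diagnostic'`` evaluates them
    from central-difference second derivatives of the saturation curves and
    the caller-supplied squared pressure-gradient magnitudes, for order-of-
    magnitude checks only (mmHg/s).
    """
    if mode == "paper":
        z = np.zeros(np.broadcast(np.asarray(po2), np.asarray(pco2)).shape)
        if np.ndim(po2) == 0 and np.ndim(pco2) == 0:
            return 0.0, 0.0
        return z, z.copy()
    if mode != "diagnostic":
        raise ValueError(f"unknown mode {mode!r}")
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()

    def d2s_o2(p):
        return (np.asarray(dso2_dpo2(p + h, pco2, params, constants))
                - np.asarray(dso2_dpo2(p - h, pco2, params, constants))) / (2 * h)

    def d2_co2(p):
        ds = (np.asarray(dsco2_dpco2(p + h, po2, params, constants))
              - np.asarray(dsco2_dpco2(p - h, po2, params, constants))) / (2 * h)
        dc = (np.asarray(dchco3_dpco2(p + h, params))
              - np.asarray(dchco3_dpco2(p - h, params))) / (2 * h)
        return ds, dc

    kHb = constants.k_O2 * params.Hb
    g_o2 = constants.alpha_O2 + kHb * np.asarray(dso2_dpo2(po2, pco2, params, constants))
    s_o2 = constants.D_HbO2 * kHb * d2s_o2(np.asarray(po2, float)) / g_o2 * grad_po2_sq

    kHbc = constants.k_CO2 * params.Hb
    ds2, dc2 = d2_co2(np.asarray(pco2, float))
    g_co2 = (constants.alpha_CO2_ml
             + kHbc * np.asarray(dsco2_dpco2(pco2, po2, params, constants))
             + np.asarray(dchco3_dpco2(pco2, params)))
    s_co2 = (constants.D_HbCO2 * kHbc * ds2 + constants.D_HCO3 * dc2) / g_co2 * grad_pco2_sq
    return s_o2, s_co2


def evaluate_state(po2, pco2, params: BloodParameters | None = None,
                   constants: GasTransportConstants | None = None,
                   mode: str = "buffer_line",
                   co2_variant: str = "kelman_grouping") -> LocalGasState:
    """Evaluate the full pointwise gas state at (PO2, PCO2).

    Vectorised over arrays; a single acid-base solve per call feeds every
    downstream quantity.
    """
    params = params or BloodParameters()
    constants = constants or GasTransportConstants()
    po2c, pco2c, n_po2, n_pco2 = clamp_pressures(po2, pco2, params)
    ab = solve_acid_base(pco2c, params)
    ph = np.asarray(ab.pH)
    po2_adj = adjusted_po2(po2c, params.T, ph, pco2c)
    pco2_adj = adjusted_pco2(pco2c, params.T, ph, po2c)
    s_o2 = kelman_saturation(po2_adj, constants)
    s_co2 = hill_sco2(pco2_adj, constants)
    c_o2 = constants.alpha_O2 * po2c + constants.k_O2 * params.Hb * np.asarray(s_o2)
    c_co2 = co2_content(pco2c, po2c, params, constants, variant=co2_variant)
    return LocalGasState(
        PO2=po2c, PCO2=pco2c, PO2_adj=po2_adj, PCO2_adj=pco2_adj, pH=ab.pH,
        SO2=s_o2, SCO2=s_co2, C_O2=c_o2, C_CO2=c_co2, C_HCO3_ml=ab.C_HCO3_ml,
        dSO2_dPO2=dso2_dpo2(po2c, pco2c, params, constants),
        dSCO2_dPCO2=dsco2_dpco2(pco2c, po2c, params, constants, mode=mode),
        dCHCO3_dPCO2=dchco3_dpco2(pco2c, params),
        Deff_O2=deff_o2(po2c, pco2c, params, constants),
        Deff_CO2=deff_co2(pco2c, po2c, params, constants, mode=mode),
        n_clamped_po2=n_po2, n_clamped_pco2=n_pco2,
    )

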