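"""Blood and gas-transport parameter sets.

All contents are expressed in mL gas (STP) per mL blood; partial pressures in
mmHg; diffusivities in m^2/s; temperature in degrees Celsius unless noted.
The defaults are the whole-blood constants used throughout the coupled
O2/CO2 transport model (venous porcine blood, Hb 0.118 g/mL, 37 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BloodParameters",
    "GasTransportConstants",
    "MMOL_TO_ML",
    "KELMAN_COEFFS",
]

#: Conversion from mmol CO2 per L blood to mL CO2 (STP) per mL blood.
MMOL_TO_ML = 0.02226

#: Empirical coefficients a1..a7 of the Kelman quartic rational saturation
#: function (adjusted PO2 in mmHg -> fractional O2 saturation).
KELMAN_COEFFS = (
    -8532.229,   # a1
    2121.401,    # a2
    -67.07399,   # a3
    935960.9,    # a4
    -31346.26,   # a5
    2396.167,    # a6
    -67.10441,   # a7
)


class ParameterError(ValueError):
    """Raised when a physical parameter violates its admissible range."""


@dataclass(frozen=True)
class BloodParameters:
    """Bulk blood properties entering the acid-base and saturation models.

    Attributes
    ----------
    Hb : float
        Total hemoglobin concentration, g Hb / mL blood.
    T : float
        Blood temperature, degrees Celsius.
    pKa : float
        Apparent acid dissociation exponent of the CO2/bicarbonate system.
        6.082 reproduces a plasma pH of 7.357 at PCO2 = 44 mmHg.
    BE : float
        Base excess, mmol/L (zero for the standard buffer line).
    unit_conv : float
        Bicarbonate conversion factor, mL CO2 (STP) per mL blood per
        mmol/L blood.
    pco2_floor, pco2_ceil : float
        Clamp bounds applied to PCO2 before any logarithmic term; the CO2
        wall boundary condition is 0 mmHg, where both the Bohr correction
        and the Henderson-Hasselbalch relation are singular.
    po2_floor : float
        Clamp bound applied to PO2 before the Haldane log term.
    """

    Hb: float = 0.118
    T: float = 37.0
    pKa: float = 6.082
    BE: float = 0.0
    unit_conv: float = MMOL_TO_ML
    pco2_floor: float = 0.5
    pco2_ceil: float = 250.0
    po2_floor: float = 0.01
    po2_ceil: float = 760.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.Hb < 0.25:
            raise ParameterError(f"Hb must lie in [0, 0.25) g/mL, got {self.Hb}")
        if not 20.0 <= self.T <= 45.0:
            raise ParameterError(f"T must lie in [20, 45] C, got {self.T}")
        if not 5.5 < self.pKa < 6.5:
            raise ParameterError(f"pKa must lie in (5.5, 6.5), got {self.pKa}")
        if self.pco2_floor <= 0.0:
            raise ParameterError("pco2_floor must be positive (log terms diverge at 0)")
        if self.pco2_ceil <= self.pco2_floor:
            raise ParameterError("pco2_ceil must exceed pco2_floor")
        if self.po2_floor <= 0.0:
            raise ParameterError("po2_floor must be positive")


@dataclass(frozen=True)
class GasTransportConstants:
    """Physical constants of the O2 and CO2 transport models.

    Diffusivities are free-solution values in whole blood; solubilities are
    Henry-law coefficients; ``k_O2`` is the Huefner coefficient (mL O2 bound
    per g of saturated Hb) and ``k_CO2`` the carbamino carrying capacity.
    """

    D_O2: float = 1.9e-9          # m^2/s, dissolved O2 in blood
    D_HbO2: float = 1.44e-11      # m^2/s, oxyhemoglobin
    D_CO2: float = 7.39e-10       # m^2/s, dissolved CO2 in blood
    D_HbCO2: float = 1.44e-11     # m^2/s, carbaminohemoglobin
    D_HCO3: float = 4.62e-10      # m^2/s, bicarbonate
    alpha_O2: float = 3.0e-5      # mL O2 / mL blood / mmHg
    alpha_CO2: float = 0.0307     # mmol / L blood / mmHg
    k_O2: float = 1.34            # mL O2 / g Hb (Huefner)
    k_CO2: float = 1.384          # mL CO2 / g Hb (carbamino capacity)
    P50_CO2: float = 265.0        # mmHg, CO2 half-saturation pressure
    n_CO2: float = 0.9942         # Hill exponent of the CO2 saturation curve
    kelman: tuple = field(default=KELMAN_COEFFS)

    def __post_init__(self) -> None:
        for name in ("D_O2", "D_HbO2", "D_CO2", "D_HbCO2", "D_HCO3",
                     "alpha_O2", "alpha_CO2", "k_O2", "k_CO2", "P50_CO2"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be strictly positive")
        if len(self.kelman) != 7:
            raise ParameterError("kelman must hold exactly seven coefficients")

    @property
    def alpha_CO2_ml(self) -> float:
        """CO2 solubility in mL CO2 (STP) / mL blood / mmHg."""
        return self.alpha_CO2 * MMOL_TO_ML
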