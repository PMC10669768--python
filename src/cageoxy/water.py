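"""Oxygen solubility and dissolved-oxygen unit conversions.

Seawater air-equilibrium O2 concentration is computed with the Garcia &
Gordon (1992) refit of the Benson & Krause data (combined temperature-
salinity equation, mL L^-1 coefficients), converted to mg L^-1 and
corrected for barometric pressure with the moist-air factor. Conversions
among mg L^-1, % air saturation, and kPa pO2 are exact linear maps at
fixed water conditions, so they round-trip losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WaterConditions",
    "o2_solubility",
    "water_vapor_pressure_kpa",
    "po2_full_saturation_kpa",
    "mgl_to_percent_sat",
    "percent_sat_to_mgl",
    "percent_sat_to_kpa",
    "kpa_to_percent_sat",
    "mgl_to_kpa",
    "kpa_to_mgl",
]

#: Mole fraction of O2 in dry air.
O2_MOLE_FRACTION = 0.2095
#: Standard atmosphere in kPa.
ATM_KPA = 101.325
#: mg O2 per mL O2 at STP.
MG_PER_ML_O2 = 1.42905

# Garcia & Gordon (1992) combined-fit coefficients, mL L^-1 units.
_GG_A = (2.00856, 3.22400, 3.99063, 4.80299, 0.978188, 1.71069)
_GG_B = (-6.24097e-3, -6.93498e-3, -6.90358e-3, -4.29155e-3)
_GG_C0 = -3.11680e-7

TEMP_RANGE = (-2.0, 40.0)
SAL_RANGE = (0.0, 40.0)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(
            f"{name}={value!r} outside valid range [{lo}, {hi}]"
        )


def water_vapor_pressure_kpa(temperature: float) -> float:
    """Saturation vapor pressure of water in kPa (Buck equation)."""
    t = temperature
    return 0.61121 * math.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def _scaled_temperature(temperature: float) -> float:
    return math.log((298.15 - temperature) / (273.15 + temperature))


def o2_solubility(
    temperature: float, salinity: float, pressure: float = 1.0
) -> float:
    """Air-equilibrium dissolved-O2 concentration in mg O2 L^-1.

    Parameters
    ----------
    temperature : float
        Water temperature in deg C, within [-2, 40].
    salinity : float
        Salinity in ppt, within [0, 40].
    pressure : float
        Barometric pressure in atm (> 0). The freshwater/seawater value at
        1 atm is scaled by the moist-air pressure factor
        ``(P - pw) / (P0 - pw)``, which is approximately linear in P.
    """
    _check_range("temperature", temperature, *TEMP_RANGE)
    _check_range("salinity", salinity, *SAL_RANGE)
    if pressure <= 0:
        raise ValueError(f"pressure={pressure!r} must be > 0 atm")
    ts = _scaled_temperature(temperature)
    ln_c = sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    ln_c += _GG_C0 * salinity * salinity
    c_1atm = math.exp(ln_c) * MG_PER_ML_O2
    pw = water_vapor_pressure_kpa(temperature)
    factor = (pressure * ATM_KPA - pw) / (ATM_KPA - pw)
    return c_1atm * factor


def po2_full_saturation_kpa(temperature: float, pressure: float = 1.0) -> float:
    """pO2 of air-saturated water in kPa: x_O2 * (P_baro - P_vapor)."""
    return O2_MOLE_FRACTION * (
        pressure * ATM_KPA - water_vapor_pressure_kpa(temperature)
    )


@dataclass(frozen=True)
class WaterConditions:
    """Temperature/salinity/pressure state with derived O2 reference values.

    ``solubility`` (mg O2 L^-1 at air equilibrium) is computed unless given
    explicitly; an explicit value lets published solubilities be injected
    verbatim, decoupling model runs from the solubility-formula choice.
    """

    temperature: float
    salinity: float = 30.0
    pressure: float = 1.0
    solubility: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_range("temperature", self.temperature, *TEMP_RANGE)
        _check_range("salinity", self.salinity, *SAL_RANGE)
        if self.pressure <= 0:
            raise ValueError(f"pressure={self.pressure!r} must be > 0 atm")
        if self.solubility is None:
            object.__setattr__(
                self,
                "solubility",
                o2_solubility(self.temperature, self.salinity, self.pressure),
            )
        elif self.solubility <= 0:
            raise ValueError(f"solubility={self.solubility!r} must be > 0")

    @property
    def po2_full_sat(self) -> float:
        """pO2 (kPa) of air-saturated water under these conditions."""
        return po2_full_saturation_kpa(self.temperature, self.pressure)

    @property
    def kpa_per_mgl(self) -> float:
        """Linear conversion factor from mg L^-1 to kPa pO2."""
        return self.po2_full_sat / self.solubility


def mgl_to_percent_sat(conc: float, wc: WaterConditions) -> float:
    """Concentration (mg L^-1) to % air saturation."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    return 100.0 * conc / wc.solubility


def percent_sat_to_mgl(pct: float, wc: WaterConditions) -> float:
    """% air saturation to concentration (mg L^-1)."""
    if pct < 0:
        raise ValueError("percent saturation must be >= 0")
    return pct / 100.0 * wc.solubility


def percent_sat_to_kpa(pct: float, wc: WaterConditions) -> float:
    """% air saturation to pO2 (kPa)."""
    if pct < 0:
        raise ValueError("percent saturation must be >= 0")
    return pct / 100.0 * wc.po2_full_sat


def kpa_to_percent_sat(po2: float, wc: WaterConditions) -> float:
    """pO2 (kPa) to % air saturation."""
    if po2 < 0:
        raise ValueError("pO2 must be >= 0")
    return 100.0 * po2 / wc.po2_full_sat


def mgl_to_kpa(conc: float, wc: WaterConditions) -> float:
    """Concentration (mg L^-1) to pO2 (kPa)."""
    return percent_sat_to_kpa(mgl_to_percent_sat(conc, wc), wc)


def kpa_to_mgl(po2: float, wc: WaterConditions) -> float:
    """pO2 (kPa) to concentration (mg L^-1)."""
    return percent_sat_to_mgl(kpa_to_percent_sat(po2, wc), wc)
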