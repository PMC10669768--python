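"""Hypoxia ceiling on aerobic metabolism: the Hill curve and its inverse.

Below full air saturation the maximum aerobic rate available to a fish is
capped by a sigmoid (Hill) function of ambient pO2:

    ceiling(pO2) = AMR / (1 + (P50 / pO2)^c)

where AMR is the normoxic active metabolic rate, P50 the half-saturation
pO2 and c the Hill coefficient. When the oxygen requirement of the
desired swimming speed (plus any SDA surcharge) exceeds the ceiling, the
fish must slow down; the realized speed solves a*exp(b*U) = ceiling - SDA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .swim import FitError, SwimCurve, mo2_at_speed

__all__ = [
    "HillParams",
    "LimitedSwim",
    "hill_ceiling",
    "min_po2_for_mo2",
    "limited_speed",
    "fit_hill",
]


@dataclass(frozen=True)
class HillParams:
    """Hill-curve parameters of the hypoxic metabolic ceiling.

    amr : mg O2 kg^-1 h^-1, normoxic asymptote
    p50 : kPa, half-saturation pO2
    hill_coef : dimensionless steepness
    """

    amr: float
    p50: float
    hill_coef: float
    temperature: float | None = None

    def __post_init__(self) -> None:
        if self.amr <= 0:
            raise ValueError("AMR must be > 0")
        if self.p50 <= 0:
            raise ValueError("P50 must be > 0")
        if self.hill_coef <= 0:
            raise ValueError("Hill coefficient must be > 0")


def hill_ceiling(params: HillParams, po2: float) -> float:
    """Maximum aerobic MO2 sustainable at ambient pO2 (kPa)."""
    if po2 <= 0:
        raise ValueError("pO2 must be > 0")
    return params.amr / (1.0 + (params.p50 / po2) ** params.hill_coef)


def min_po2_for_mo2(params: HillParams, target_mo2: float) -> float:
    """Smallest pO2 (kPa) at which ``target_mo2`` fits under the ceiling.

    Closed-form inverse of the Hill curve; the target must lie strictly
    inside (0, AMR) since AMR is only reached asymptotically.
    """
    if target_mo2 <= 0:
        raise ValueError("target MO2 must be > 0")
    if target_mo2 >= params.amr:
        raise ValueError(
            f"target MO2 {target_mo2:.4g} is at or above the AMR asymptote "
            f"{params.amr:.4g}; no finite pO2 can sustain it"
        )
    ratio = params.amr / target_mo2 - 1.0
    return params.p50 / ratio ** (1.0 / params.hill_coef)


class LimitedSwim(NamedTuple):
    """Outcome of capping a desired swimming speed by the hypoxia ceiling."""

    speed: float
    mo2: float
    limited: bool
    below_maintenance: bool


def limited_speed(
    curve: SwimCurve,
    params: HillParams,
    po2: float,
    desired_speed: float,
    fed: bool = False,
    sda_fraction: float = 0.40,
) -> LimitedSwim:
    """Realized (speed, MO2) at ambient pO2 for a desired swimming speed.

    If the oxygen demand at ``desired_speed`` fits under the Hill ceiling
    the desired speed stands. Otherwise total uptake equals the ceiling;
    the obligatory SDA surcharge (if fed) is paid first and swimming gets
    the remainder, so the realized speed solves a*exp(b*U) = ceiling - SDA,
    clamped to [0, desired_speed]. If the ceiling cannot even cover
    maintenance (SMR + SDA), speed is 0 and ``below_maintenance`` is set.
    """
    if po2 <= 0:
        raise ValueError("pO2 must be > 0")
    if desired_speed < 0:
        raise ValueError("desired speed must be >= 0")
    demand = mo2_at_speed(curve, desired_speed, fed, sda_fraction)
    ceiling = hill_ceiling(params, po2)
    if demand <= ceiling:
        return LimitedSwim(desired_speed, demand, False, False)
    sda_term = sda_fraction * curve.a if fed else 0.0
    available = ceiling - sda_term
    maintenance = curve.a
    if available <= maintenance or curve.b == 0:
        return LimitedSwim(0.0, ceiling, True, available < maintenance)
    speed = math.log(available / curve.a) / curve.b
    speed = min(max(speed, 0.0), desired_speed)
    return LimitedSwim(speed, ceiling, True, False)


def fit_hill(
    points: Sequence[tuple[float, float]] | np.ndarray,
    amr: float,
    *,
    temperature: float | None = None,
) -> HillParams:
    """Least-squares (P50, Hill coefficient) with AMR held fixed.

    ``points`` are (pO2 kPa, MO2) pairs. AMR comes from normoxia trials
    and is not re-estimated. The data must bracket the half-saturation
    level AMR/2, otherwise the sigmoid is underdetermined.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitError("need at least 3 (pO2, MO2) points")
    if amr <= 0:
        raise FitError("AMR must be > 0")
    po2, mo2 = arr[:, 0], arr[:, 1]
    if np.any(po2 <= 0):
        raise FitError("pO2 values must be > 0")
    half = amr / 2.0
    if not (mo2.min() < half < mo2.max()):
        raise FitError(
            "points must span both sides of the inflection (AMR/2)"
        )

    def model(x, p50, c):
        return amr / (1.0 + (p50 / x) ** c)

    # initial P50: pO2 whose MO2 is closest to AMR/2
    p50_0 = float(po2[np.argmin(np.abs(mo2 - half))])
    (p50, c), _ = curve_fit(
        model,
        po2,
        mo2,
        p0=(p50_0, 4.0),
        bounds=([1e-6, 1e-3], [np.inf, 100.0]),
        maxfev=10000,
    )
    return HillParams(
        amr=amr, p50=float(p50), hill_coef=float(c), temperature=temperature
    )
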