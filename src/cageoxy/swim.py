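"""Swimming energetics: the exponential MO2-speed curve and derived rates.

Oxygen uptake of a steadily swimming fish rises exponentially with speed,
MO2(U) = a * exp(b*U), with the intercept ``a`` equal to the standard
metabolic rate (SMR) and ``b`` the speed sensitivity per BL s^-1. From the
fitted curve follow the cost of transport COT(U) = MO2/U, its minimizer
Uopt = 1/b, the Brett critical swimming speed from an incremental trial,
allometric mass adjustment of rates, and the Q10 temperature coefficient.
A fed fish carries a specific-dynamic-action (SDA) surcharge expressed as
a fixed fraction of SMR added to the swimming requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


class FitError(ValueError):
    """Raised when a regression cannot be performed on the given data."""


@dataclass(frozen=True)
class SwimCurve:
    """Fitted exponential swim curve MO2 = a * exp(b * U).

    a : mg O2 kg^-1 h^-1, zero-speed intercept (= SMR)
    b : per BL s^-1, exponential speed coefficient (>= 0; 0 is the
        degenerate flat curve)
    """

    a: float
    b: float
    temperature: float | None = None
    n_fish: int | None = None
    mass_mean: float | None = None
    length_mean: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"intercept a={self.a!r} must be > 0")
        if self.b < 0:
            raise ValueError(f"exponent b={self.b!r} must be >= 0")

    @property
    def smr(self) -> float:
        """Standard metabolic rate: the curve extrapolated to speed 0."""
        return self.a


@dataclass(frozen=True)
class SwimTrial:
    """Incremental-velocity trial summary for the Brett Ucrit formula.

    completed_speed : highest fully completed speed (BL s^-1)
    increment : velocity step between increments (BL s^-1)
    time_in_final : minutes swum in the fatigue increment
    increment_duration : full duration of one increment (minutes)
    """

    completed_speed: float
    increment: float
    time_in_final: float
    increment_duration: float

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("speed increment must be > 0")
        if self.increment_duration <= 0:
            raise ValueError("increment duration must be > 0")
        if not (0 <= self.time_in_final <= self.increment_duration):
            raise ValueError(
                "time in final increment must lie within "
                "[0, increment_duration]"
            )


@dataclass(frozen=True)
class MetabolicSummary:
    """Headline rates and speeds for one fish or one temperature group."""

    smr: float
    amr: float
    ucrit: float | None = None
    uopt: float | None = None
    sda_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.amr < self.smr:
            raise ValueError("AMR must be >= SMR")
        if self.sda_fraction < 0:
            raise ValueError("SDA fraction must be >= 0")

    @property
    def fams(self) -> float:
        """Factorial aerobic metabolic scope AMR/SMR."""
        return self.amr / self.smr

    @property
    def ams(self) -> float:
        """Absolute aerobic metabolic scope AMR - SMR."""
        return self.amr - self.smr


def fit_swim_curve(
    records: Sequence[tuple[float, float]] | np.ndarray,
    *,
    nonlinear: bool = False,
    **meta,
) -> SwimCurve:
    """Fit MO2 = a*exp(b*U) to (speed, MO2) records.

    The primary fit is a linear regression of ln(MO2) on speed, which is
    closed-form, deterministic, and matches the multiplicative error
    structure of respirometry data. ``nonlinear=True`` refines it with an
    untransformed least-squares fit (sensitivity option).
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise FitError("need at least 3 (speed, MO2) records")
    speed, mo2 = arr[:, 0], arr[:, 1]
    if np.any(speed < 0):
        raise FitError("speeds must be non-negative")
    if np.any(mo2 <= 0):
        raise FitError("MO2 values must be positive")
    slope, intercept = np.polyfit(speed, np.log(mo2), 1)
    a, b = math.exp(intercept), float(slope)
    if nonlinear:
        (a, b), _ = curve_fit(
            lambda u, a_, b_: a_ * np.exp(b_ * u), speed, mo2, p0=(a, b)
        )
    # tiny negative slopes from noise on a flat curve collapse to b = 0
    if b < 0 and not nonlinear:
        b = max(b, 0.0) if abs(b) < 1e-12 else b
    if b < 0:
        raise FitError(
            f"fitted exponent b={b:.4g} is negative; MO2 must not "
            "decrease with speed"
        )
    return SwimCurve(a=a, b=b, **meta)


def mo2_at_speed(
    curve: SwimCurve,
    speed: float,
    fed: bool = False,
    sda_fraction: float = 0.40,
) -> float:
    """MO2 (mg O2 kg^-1 h^-1) at a swimming speed, with optional SDA.

    The SDA surcharge of a fed fish is additive: ``sda_fraction * SMR`` on
    top of the swimming requirement, independent of speed.
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    mo2 = curve.a * math.exp(curve.b * speed)
    if fed:
        mo2 += sda_fraction * curve.a
    return mo2


def uopt(curve: SwimCurve) -> float:
    """Optimal swimming speed (BL s^-1), the COT minimizer 1/b."""
    if curve.b <= 0:
        raise ValueError(
            "optimal speed is undefined for a flat swim curve (b <= 0)"
        )
    return 1.0 / curve.b


def cost_of_transport(curve: SwimCurve, speed: float) -> float:
    """Cost of transport: MO2 per body length, MO2(U)/U (unfed).

    Undefined at speed 0 (a resting fish covers no distance); callers must
    pass speed > 0.
    """
    if speed <= 0:
        raise ValueError("COT is undefined at zero or negative speed")
    return mo2_at_speed(curve, speed) / speed


def ucrit(trial: SwimTrial) -> float:
    """Brett critical swimming speed u_i + (t_i / t_ii) * u_ii (BL s^-1)."""
    return (
        trial.completed_speed
        + trial.time_in_final / trial.increment_duration * trial.increment
    )


def mass_adjust(
    mo2: float,
    mass: float,
    target_mass: float = 1.5,
    exponent: float = 0.89,
) -> float:
    """Adjust a mass-specific MO2 to a common body mass.

    MO2_adj = MO2 * (mass / target_mass)^(1 - A) with allometric mass
    exponent A (0.89 for rainbow trout). Identity at A = 1 or at the
    target mass.
    """
    if mass <= 0 or target_mass <= 0:
        raise ValueError("masses must be > 0")
    return mo2 * (mass / target_mass) ** (1.0 - exponent)


def q10(rate1: float, rate2: float, t1: float, t2: float) -> float:
    """Q10 temperature coefficient (rate2/rate1)^(10/(t2-t1))."""
    if rate1 <= 0 or rate2 <= 0:
        raise ValueError("rates must be > 0")
    if t1 == t2:
        raise ValueError("Q10 requires two distinct temperatures")
    return (rate2 / rate1) ** (10.0 / (t2 - t1))
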