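"""Canned case study: a 160 m-circumference cage at 10, 15 and 20 deg C.

The reference scenario is a standard-to-large sea cage (circumference
160 m, depth 8 m, volume 16,297.5 m^3, diameter 50.9 m) stocked at
25 kg m^-3 with 1.5 kg / 45 cm rainbow trout at 30 ppt and 1 atm, fed
(SDA 40% of SMR) and swimming at Upref = 1.1 BL s^-1, with a 5 cm s^-1
current for the transect series. Swim-curve and Hill constants are the
mass-adjusted laboratory determinations per temperature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .cage import (
    CageScenario,
    CageSpec,
    StockingSpec,
    cs1_depletion,
    cs2_profile,
    cs3_flow_sweep,
)
from .hypoxia import HillParams
from .swim import SwimCurve
from .water import WaterConditions

__all__ = ["CASE_STUDY_CONSTANTS", "case_study_scenario", "run_case_study"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class _TempParams:
    smr: float
    exponent: float
    amr: float
    p50: float
    hill_coef: float
    solubility: float  # published reference value, mg L^-1


#: Per-temperature laboratory constants used by the reference case study.
CASE_STUDY_CONSTANTS: dict[float, _TempParams] = {
    10.0: _TempParams(54.8, 1.114, 298.2, 6.50, 3.50, 9.39),
    15.0: _TempParams(60.5, 0.909, 414.9, 6.04, 5.51, 8.44),
    20.0: _TempParams(99.8, 0.646, 393.1, 6.24, 5.70, 7.63),
}

CAGE_CIRCUMFERENCE = 160.0
CAGE_DEPTH = 8.0
FISH_MASS = 1.5
FISH_LENGTH = 45.0
DENSITY = 25.0
SDA_FRACTION = 0.40
UPREF = 1.1
CURRENT_CM_S = 5.0
SALINITY = 30.0
PRESSURE_ATM = 1.0

#: Published case-study reference values, used only to flag deviations.
_REFERENCE_TABLE = {
    "do_threshold_mg_l": {10.0: 4.86, 15.0: 5.57, 20.0: 6.13},
    "cs1_threshold_min": {10.0: 58, 15.0: 36, 20.0: 19},
    "cs2_downstream_mg_l": {10.0: 7.9, 15.0: 6.9, 20.0: 6.1},
    "cs2_max_cage_m": {10.0: 155.7, 15.0: 98.0, 20.0: 29.6},
    "cs3_min_flow_cm_s": {10.0: 1.5, 15.0: 2.2, 20.0: 5.6},
}


def case_study_scenario(
    temperature: float,
    fed: bool = True,
    density: float = DENSITY,
    use_published_solubility: bool = True,
) -> CageScenario:
    """Build the reference scenario for one of the three temperatures."""
    try:
        p = CASE_STUDY_CONSTANTS[float(temperature)]
    except KeyError:
        raise ValueError(
            f"case study is defined at 10, 15, 20 degC, not {temperature}"
        ) from None
    water = WaterConditions(
        temperature=temperature,
        salinity=SALINITY,
        pressure=PRESSURE_ATM,
        solubility=p.solubility if use_published_solubility else None,
    )
    return CageScenario(
        water=water,
        cage=CageSpec(CAGE_CIRCUMFERENCE, CAGE_DEPTH),
        stocking=StockingSpec(
            mean_mass=FISH_MASS, mean_length=FISH_LENGTH, density=density
        ),
        curve=SwimCurve(a=p.smr, b=p.exponent, temperature=temperature),
        hill=HillParams(
            amr=p.amr, p50=p.p50, hill_coef=p.hill_coef,
            temperature=temperature,
        ),
        upref=UPREF,
        fed=fed,
        sda_fraction=SDA_FRACTION,
        current_velocity=CURRENT_CM_S,
    )


def run_case_study(
    fed: bool = True,
    density: float = DENSITY,
    rounding: str = "table3",
    dt: float = 1.0,
    flag_deviations: bool = True,
) -> pd.DataFrame:
    """Run all three calculation series at 10/15/20 deg C.

    Returns a summary frame (rows: solubility, DO threshold, CS1 crossing,
    CS2 downstream edge and max cage, CS3 minimum flow; columns:
    temperature). ``rounding='table3'`` floors crossing minutes and trims
    concentrations/flows to presentation precision; ``'full'`` keeps full
    precision so repeated runs are byte-identical.
    """
    if rounding not in ("table3", "full"):
        raise ValueError("rounding must be 'table3' or 'full'")
    cols: dict[float, dict[str, float | None]] = {}
    for temp in sorted(CASE_STUDY_CONSTANTS):
        scen = case_study_scenario(temp, fed=fed, density=density)
        cs1 = cs1_depletion(scen, swim_mode="upref", dt=dt, horizon=24.0)
        cs2 = cs2_profile(scen)
        cs3 = cs3_flow_sweep(scen, policy="upref_floor")
        cols[temp] = {
            "solubility_mg_l": scen.water.solubility,
            "do_threshold_mg_l": scen.threshold_conc,
            "cs1_threshold_min": cs1.threshold_crossing_min,
            "cs2_downstream_mg_l": cs2.downstream_edge_conc,
            "cs2_max_cage_m": cs2.max_diameter_to_threshold,
            "cs3_min_flow_cm_s": cs3.min_flow_cm_s,
        }
    frame = pd.DataFrame(cols)
    if flag_deviations:
        _flag_deviations(frame)
    if rounding == "table3":
        frame = _round_table3(frame)
    return frame


def _round_table3(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    digits = {
        "solubility_mg_l": 2,
        "do_threshold_mg_l": 2,
        "cs2_downstream_mg_l": 1,
        "cs2_max_cage_m": 1,
        "cs3_min_flow_cm_s": 1,
    }
    for row, nd in digits.items():
        out.loc[row] = out.loc[row].round(nd)
    out.loc["cs1_threshold_min"] = out.loc["cs1_threshold_min"].map(
        lambda v: math.floor(v) if pd.notna(v) else v
    )
    return out


def _flag_deviations(frame: pd.DataFrame) -> None:
    for row, per_temp in _REFERENCE_TABLE.items():
        for temp, ref in per_temp.items():
            ours = frame.at[row, temp]
            if ours is None or pd.isna(ours):
                logger.warning(
                    "%s at %g degC: not reached (reference %s)",
                    row, temp, ref,
                )
                continue
            tol = max(0.05, 0.02 * abs(ref))
            if abs(ours - ref) > tol:
                logger.warning(
                    "%s at %g degC deviates from the published value: "
                    "%.4g vs %.4g",
                    row, temp, ours, ref,
                )
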