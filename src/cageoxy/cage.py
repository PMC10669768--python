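"""Sea-cage oxygen budget: geometry, stocking, DO threshold, and the three
calculation series.

The cage is a cylinder specified by circumference and depth, stocked
uniformly at density rho (kg m^-3). Fish deplete oxygen at the rate given
by the swim curve (plus SDA when fed), capped by the hypoxia ceiling as
the cage water deoxygenates. Three calculation series describe the
resulting oxygen conditions:

CS1  no flow: concentration versus time, linear decline while the ceiling
     is slack, concave tail once the ceiling binds;
CS2  fixed current: concentration versus distance along the transect,
     with travel time x/v acting as the clock;
CS3  current sweep: downstream-edge concentration versus current velocity
     under two swim policies, and the minimum flow that keeps the whole
     cage above the feed-utilization DO threshold.

Unit bridge used throughout: MO2 (mg O2 kg^-1 h^-1) times rho (kg m^-3)
gives mg m^-3 h^-1; divide by 1000 for mg L^-1 h^-1 and by a further 3600
for per-second rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hypoxia import HillParams, LimitedSwim, limited_speed, min_po2_for_mo2
from .swim import FitError, SwimCurve, mo2_at_speed
from .water import WaterConditions

__all__ = [
    "CageSpec",
    "StockingSpec",
    "CageScenario",
    "ThresholdLine",
    "DEFAULT_THRESHOLD_LINE",
    "cage_geometry",
    "fish_density",
    "do_threshold",
    "fit_threshold_line",
    "cs1_depletion",
    "cs1_threshold_time_analytic",
    "cs2_profile",
    "cs3_flow_sweep",
    "scenario_from_dict",
    "CS1Result",
    "CS2Result",
    "CS3Result",
]

#: fraction of air saturation below which the cage is treated as anoxic
ANOXIA_FRACTION = 0.01


@dataclass(frozen=True)
class CageSpec:
    """Cylindrical cage sized by circumference (m) and depth (m)."""

    circumference: float
    depth: float

    def __post_init__(self) -> None:
        if self.circumference <= 0 or self.depth <= 0:
            raise ValueError("circumference and depth must be > 0")

    @property
    def diameter(self) -> float:
        return self.circumference / math.pi

    @property
    def radius(self) -> float:
        return self.circumference / (2.0 * math.pi)

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.depth


def cage_geometry(circumference: float, depth: float) -> CageSpec:
    """Cage volume and diameter from circumference and depth."""
    return CageSpec(circumference=circumference, depth=depth)


@dataclass(frozen=True)
class StockingSpec:
    """Fish stocking: count and mean size, or a density given directly."""

    mean_mass: float
    mean_length: float
    count: float | None = None
    density: float | None = None

    def __post_init__(self) -> None:
        if self.mean_mass <= 0 or self.mean_length <= 0:
            raise ValueError("mean mass and length must be > 0")
        if self.count is None and self.density is None:
            raise ValueError("give either a fish count or a density")
        if self.count is not None and self.count < 0:
            raise ValueError("fish count must be >= 0")
        if self.density is not None and self.density < 0:
            raise ValueError("density must be >= 0")

    def resolve_density(self, volume: float) -> float:
        """Stocking density kg m^-3, derived from count if not given."""
        if self.density is not None:
            return self.density
        return fish_density(self.count, self.mean_mass, volume)


def fish_density(count: float, mean_mass: float, volume: float) -> float:
    """Stocking density rho = Q * m / Vol (kg m^-3)."""
    if volume <= 0:
        raise ValueError("cage volume must be > 0")
    if count < 0 or mean_mass <= 0:
        raise ValueError("count must be >= 0 and mean mass > 0")
    return count * mean_mass / volume


@dataclass(frozen=True)
class ThresholdLine:
    """Linear feed-utilization DO threshold in % air saturation vs deg C.

    Defaults are the regression through published salmonid feed-intake
    thresholds: %DO = 2.875 * T + 22.85, clamped to at most 100%.
    """

    slope: float = 2.875
    intercept: float = 22.85

    def percent(self, temperature: float) -> float:
        pct = self.slope * temperature + self.intercept
        if pct <= 0:
            raise ValueError(
                f"threshold line gives non-positive %DO at T={temperature}"
            )
        return min(pct, 100.0)

    def conc(self, temperature: float, solubility: float) -> float:
        return self.percent(temperature) / 100.0 * solubility


DEFAULT_THRESHOLD_LINE = ThresholdLine()


def do_threshold(
    temperature: float,
    solubility: float,
    line: ThresholdLine = DEFAULT_THRESHOLD_LINE,
) -> tuple[float, float]:
    """Feed-utilization DO threshold as (% air sat, mg L^-1)."""
    pct = line.percent(temperature)
    return pct, pct / 100.0 * solubility


def fit_threshold_line(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> ThresholdLine:
    """OLS fit of %DO threshold against temperature."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise FitError("need at least 2 (temperature, %DO) points")
    t, pct = arr[:, 0], arr[:, 1]
    if np.ptp(t) == 0:
        raise FitError("temperatures must not all be identical")
    slope, intercept = np.polyfit(t, pct, 1)
    return ThresholdLine(slope=float(slope), intercept=float(intercept))


@dataclass(frozen=True)
class CageScenario:
    """Complete parameterization of one cage simulation."""

    water: WaterConditions
    cage: CageSpec
    stocking: StockingSpec
    curve: SwimCurve
    hill: HillParams
    upref: float = 1.1
    fed: bool = False
    sda_fraction: float = 0.40
    current_velocity: float = 0.0  # cm s^-1
    inlet_o2: float | None = None  # mg L^-1, defaults to solubility
    threshold_line: ThresholdLine = field(default=DEFAULT_THRESHOLD_LINE)

    def __post_init__(self) -> None:
        if self.upref <= 0:
            raise ValueError("Upref must be > 0")
        if self.sda_fraction < 0:
            raise ValueError("SDA fraction must be >= 0")
        if self.current_velocity < 0:
            raise ValueError("current velocity must be >= 0")
        if self.inlet_o2 is None:
            object.__setattr__(self, "inlet_o2", self.water.solubility)
        elif not (0 < self.inlet_o2 <= self.water.solubility):
            raise ValueError(
                "inlet O2 must lie in (0, solubility]"
            )

    @property
    def density(self) -> float:
        """Stocking density kg m^-3."""
        return self.stocking.resolve_density(self.cage.volume)

    @property
    def threshold_conc(self) -> float:
        """Feed-utilization DO threshold in mg L^-1."""
        return self.threshold_line.conc(
            self.water.temperature, self.water.solubility
        )

    @property
    def anoxia_conc(self) -> float:
        return ANOXIA_FRACTION * self.water.solubility

    def bl_speed(self, v_cm_s: float) -> float:
        """Convert a current velocity (cm s^-1) to BL s^-1 via fish length."""
        return v_cm_s / self.stocking.mean_length

    def step_uptake(self, conc: float, desired_speed: float) -> LimitedSwim:
        """Hill-capped (speed, MO2) at a cage O2 concentration (mg L^-1)."""
        if conc <= 0:
            return LimitedSwim(0.0, 0.0, True, True)
        po2 = conc * self.water.kpa_per_mgl
        return limited_speed(
            self.curve,
            self.hill,
            po2,
            desired_speed,
            self.fed,
            self.sda_fraction,
        )


def _desired_speed(scenario: CageScenario, swim_mode: str) -> float:
    if swim_mode == "rest":
        return 0.0
    if swim_mode == "upref":
        return scenario.upref
    raise ValueError(f"unknown swim mode {swim_mode!r}; use 'rest' or 'upref'")


def _interp_crossing(t0: float, c0: float, t1: float, c1: float,
                     level: float) -> float:
    if c0 == c1:
        return t1
    return t0 + (c0 - level) / (c0 - c1) * (t1 - t0)


@dataclass
class CS1Result:
    """Oxygen depletion over time in a cage with no flow-through."""

    time_h: np.ndarray
    conc: np.ndarray
    speed_bl_s: np.ndarray
    mo2: np.ndarray
    threshold_percent: float
    threshold_conc: float
    threshold_crossing_min: float | None
    anoxia_crossing_min: float | None

    @property
    def threshold_crossing_min_floor(self) -> int | None:
        """Crossing time floored to whole minutes (table presentation)."""
        if self.threshold_crossing_min is None:
            return None
        return int(math.floor(self.threshold_crossing_min))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_min": self.time_h * 60.0,
                "o2_mg_l": self.conc,
                "speed_bl_s": self.speed_bl_s,
                "mo2_mg_kg_h": self.mo2,
            }
        )


def cs1_depletion(
    scenario: CageScenario,
    swim_mode: str = "upref",
    dt: float = 1.0,
    horizon: float = 24.0,
    record_every: float = 60.0,
) -> CS1Result:
    """CS1: forward-Euler oxygen depletion with no water exchange.

    Concentration declines linearly at MO2 * rho / 1000 mg L^-1 h^-1 while
    the hypoxia ceiling is slack; once ambient pO2 falls below the minimum
    required for the desired speed, the per-step MO2 is the Hill ceiling,
    giving the concave tail. Crossing times (DO threshold, anoxia) are
    linearly interpolated within the step; `horizon` is in hours, `dt` and
    `record_every` in seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    desired = _desired_speed(scenario, swim_mode)
    rho = scenario.density
    thr = scenario.threshold_conc
    anox = scenario.anoxia_conc
    horizon_s = horizon * 3600.0

    times, concs, speeds, mo2s = [], [], [], []
    conc = scenario.inlet_o2
    t = 0.0
    thr_cross = None
    anox_cross = None
    next_record = 0.0
    while True:
        lim = scenario.step_uptake(conc, desired)
        if t >= next_record:
            times.append(t)
            concs.append(conc)
            speeds.append(lim.speed)
            mo2s.append(lim.mo2)
            next_record += record_every
        if t >= horizon_s:
            break
        rate = lim.mo2 * rho / 3.6e6  # mg L^-1 s^-1
        new = max(conc - rate * dt, 0.0)
        t_new = t + dt
        if thr_cross is None and conc > thr >= new:
            thr_cross = _interp_crossing(t, conc, t_new, new, thr) / 60.0
        if anox_cross is None and conc > anox >= new:
            anox_cross = _interp_crossing(t, conc, t_new, new, anox) / 60.0
        conc, t = new, t_new

    return CS1Result(
        time_h=np.asarray(times) / 3600.0,
        conc=np.asarray(concs),
        speed_bl_s=np.asarray(speeds),
        mo2=np.asarray(mo2s),
        threshold_percent=scenario.threshold_line.percent(
            scenario.water.temperature
        ),
        threshold_conc=thr,
        threshold_crossing_min=thr_cross,
        anoxia_crossing_min=anox_cross,
    )


def cs1_threshold_time_analytic(
    scenario: CageScenario, swim_mode: str = "upref"
) -> float | None:
    """Closed-form CS1 threshold crossing (minutes), linear phase only.

    Valid when the DO threshold lies above the concentration at which the
    hypoxia ceiling starts to bind (the usual case: feed-utilization
    thresholds sit far above Pcrit). Returns None if the cap binds first,
    or if rho = 0.
    """
    desired = _desired_speed(scenario, swim_mode)
    demand = mo2_at_speed(
        scenario.curve, desired, scenario.fed, scenario.sda_fraction
    )
    rho = scenario.density
    if rho == 0:
        return None
    thr = scenario.threshold_conc
    if thr >= scenario.inlet_o2:
        return 0.0
    if demand < scenario.hill.amr:
        cap_onset_kpa = min_po2_for_mo2(scenario.hill, demand)
        cap_onset_conc = cap_onset_kpa / scenario.water.kpa_per_mgl
        if thr < cap_onset_conc:
            return None
    else:
        return None
    rate = demand * rho / 1000.0  # mg L^-1 h^-1
    return (scenario.inlet_o2 - thr) / rate * 60.0


@dataclass
class CS2Result:
    """Oxygen concentration along the cage transect at fixed current."""

    x_m: np.ndarray
    conc: np.ndarray
    speed_bl_s: np.ndarray
    mo2: np.ndarray
    downstream_edge_conc: float
    max_diameter_to_threshold: float | None
    threshold_conc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_m": self.x_m,
                "o2_mg_l": self.conc,
                "speed_bl_s": self.speed_bl_s,
                "mo2_mg_kg_h": self.mo2,
            }
        )


def _transect_conc(
    scenario: CageScenario,
    v_cm_s: float,
    desired_speed: float,
    distance: float,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Euler integration of concentration along travel distance.

    Plug flow: a parcel entering at the upstream edge spends x / v seconds
    reaching distance x, during which the uniformly distributed fish draw
    it down exactly as in CS1.
    """
    v = v_cm_s / 100.0  # m s^-1
    rho = scenario.density
    xs = np.linspace(0.0, distance, n_steps + 1)
    dt = (distance / n_steps) / v
    concs = np.empty_like(xs)
    speeds = np.empty_like(xs)
    mo2s = np.empty_like(xs)
    conc = scenario.inlet_o2
    for i, _x in enumerate(xs):
        lim = scenario.step_uptake(conc, desired_speed)
        concs[i] = conc
        speeds[i] = lim.speed
        mo2s[i] = lim.mo2
        if i < n_steps:
            conc = max(conc - lim.mo2 * rho / 3.6e6 * dt, 0.0)
    return xs, concs, speeds, mo2s


def cs2_profile(
    scenario: CageScenario,
    n_steps: int = 2000,
    max_extension: float = 50.0,
) -> CS2Result:
    """CS2: oxygen distribution through the cage at the scenario current.

    The profile is reported over [0, diameter]; the integration continues
    past the downstream edge (up to ``max_extension`` diameters) to locate
    the largest cage diameter whose downstream edge still meets the DO
    threshold.
    """
    v = scenario.current_velocity
    if v <= 0:
        raise ValueError(
            "CS2 requires a positive current velocity; with no flow use "
            "cs1_depletion"
        )
    desired = scenario.upref
    d = scenario.cage.diameter
    thr = scenario.threshold_conc
    xs, concs, speeds, mo2s = _transect_conc(scenario, v, desired, d, n_steps)
    downstream = float(concs[-1])

    max_diam: float | None = None
    below = np.nonzero(concs <= thr)[0]
    if scenario.inlet_o2 <= thr:
        max_diam = 0.0
    elif below.size:
        i = below[0]
        max_diam = _interp_crossing(
            xs[i - 1], concs[i - 1], xs[i], concs[i], thr
        )
    else:
        # extend past the cage, coarse steps of the same length
        v_ms = v / 100.0
        dx = d / n_steps
        dt = dx / v_ms
        conc = downstream
        x = d
        rho = scenario.density
        while x < max_extension * d:
            lim = scenario.step_uptake(conc, desired)
            new = max(conc - lim.mo2 * rho / 3.6e6 * dt, 0.0)
            if new <= thr < conc:
                max_diam = _interp_crossing(x, conc, x + dx, new, thr)
                break
            conc, x = new, x + dx

    return CS2Result(
        x_m=xs,
        conc=concs,
        speed_bl_s=speeds,
        mo2=mo2s,
        downstream_edge_conc=downstream,
        max_diameter_to_threshold=max_diam,
        threshold_conc=thr,
    )


@dataclass
class CS3Result:
    """Downstream-edge concentration versus current velocity."""

    v_cm_s: np.ndarray
    conc: np.ndarray
    speed_bl_s: np.ndarray
    min_flow_cm_s: float | None
    threshold_conc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v_cm_s": self.v_cm_s,
                "o2_mg_l": self.conc,
                "speed_bl_s": self.speed_bl_s,
            }
        )


def _policy_speed(scenario: CageScenario, v_cm_s: float, policy: str) -> float:
    swim_bl = scenario.bl_speed(v_cm_s)
    if policy == "match_current":
        return swim_bl
    if policy == "upref_floor":
        return max(scenario.upref, swim_bl)
    raise ValueError(
        f"unknown policy {policy!r}; use 'match_current' or 'upref_floor'"
    )


def _downstream_conc(
    scenario: CageScenario, v_cm_s: float, policy: str, n_steps: int = 500
) -> tuple[float, float]:
    """(downstream-edge conc, swim speed) at one current velocity.

    Fast closed-form path when the hypoxia ceiling stays slack over the
    whole transect; Euler fallback otherwise.
    """
    desired = _policy_speed(scenario, v_cm_s, policy)
    demand = mo2_at_speed(
        scenario.curve, desired, scenario.fed, scenario.sda_fraction
    )
    residence = scenario.cage.diameter / (v_cm_s / 100.0)  # s
    linear_end = (
        scenario.inlet_o2 - demand * scenario.density / 3.6e6 * residence
    )
    if demand < scenario.hill.amr and linear_end > 0:
        cap_kpa = min_po2_for_mo2(scenario.hill, demand)
        if linear_end * scenario.water.kpa_per_mgl >= cap_kpa:
            return linear_end, desired
    _, concs, speeds, _ = _transect_conc(
        scenario, v_cm_s, desired, scenario.cage.diameter, n_steps
    )
    return float(concs[-1]), float(speeds[-1])


def cs3_flow_sweep(
    scenario: CageScenario,
    policy: str = "upref_floor",
    v_grid: Sequence[float] | None = None,
    refine_tol: float = 0.01,
) -> CS3Result:
    """CS3: downstream-edge oxygen versus current velocity (cm s^-1).

    ``min_flow_cm_s`` is the smallest velocity whose downstream edge still
    meets the DO threshold, located on the grid and refined by bisection
    to ``refine_tol`` cm s^-1.
    """
    if v_grid is None:
        v_grid = np.arange(0.5, 20.0 + 1e-9, 0.5)
    vs = np.asarray(list(v_grid), dtype=float)
    if vs.size == 0:
        raise ValueError("velocity grid must not be empty")
    if np.any(vs <= 0) or np.any(np.diff(vs) <= 0):
        raise ValueError("velocity grid must be positive and ascending")

    concs = np.empty_like(vs)
    speeds = np.empty_like(vs)
    for i, v in enumerate(vs):
        concs[i], speeds[i] = _downstream_conc(scenario, v, policy)

    thr = scenario.threshold_conc
    min_flow: float | None = None

    def ok(v: float) -> bool:
        return _downstream_conc(scenario, v, policy)[0] >= thr

    above = np.nonzero(concs >= thr)[0]
    if above.size:
        hi = vs[above[0]]
        lo = vs[above[0] - 1] if above[0] > 0 else hi / 2.0
        # expand the lower bracket below the grid if needed
        while above[0] == 0 and lo > refine_tol and ok(lo):
            hi = lo
            lo /= 2.0
        if not ok(lo):
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                if ok(mid):
                    hi = mid
                else:
                    lo = mid
            min_flow = hi
        else:
            min_flow = lo
    return CS3Result(
        v_cm_s=vs,
        conc=concs,
        speed_bl_s=speeds,
        min_flow_cm_s=min_flow,
        threshold_conc=thr,
    )


def scenario_from_dict(d: dict) -> CageScenario:
    """Build a CageScenario from a plain (YAML/JSON-shaped) mapping."""
    try:
        water = WaterConditions(**d["water"])
        cage = CageSpec(**d["cage"])
        stocking = StockingSpec(**d["stocking"])
        curve = SwimCurve(**d["curve"])
        hill = HillParams(**d["hill"])
    except KeyError as exc:
        raise ValueError(f"scenario is missing section {exc}") from exc
    extra = {
        k: d[k]
        for k in ("upref", "fed", "sda_fraction", "current_velocity",
                  "inlet_o2")
        if k in d
    }
    if "threshold_line" in d:
        extra["threshold_line"] = ThresholdLine(**d["threshold_line"])
    return CageScenario(
        water=water, cage=cage, stocking=stocking, curve=curve, hill=hill,
        **extra,
    )
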