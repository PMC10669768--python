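"""Seeded synthetic-data generators emulating the laboratory protocols.

Three generators produce every input the analysis modules consume, so the
full pipeline is testable without measured data:

* incremental swim trials (exponential MO2-speed truth, lognormal noise,
  fatigue drawn to hit a target Ucrit),
* self-induced-hypoxia O2 traces (a fish at fixed speed draws the chamber
  down; uptake is demand until the Hill ceiling binds, then the ceiling),
* long feeding series in which daily meals superpose an SDA kernel onto
  RMR until an equilibrium plateau emerges.

All randomness flows from one integer seed through a single Generator, so
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .hypoxia import HillParams, hill_ceiling
from .respirometry import RespirometryTrace, SdaSeries
from .swim import SwimCurve, mo2_at_speed
from .water import WaterConditions

__all__ = [
    "GeneratorConfig",
    "gen_swim_trials",
    "gen_hypoxia_trace",
    "gen_sda_series",
    "hypoxia_points_from_trace",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared knobs for the synthetic generators.

    noise_cv is the coefficient of variation of multiplicative lognormal
    measurement noise (0.03 is typical of optode-based slope estimates).
    Swim trials start at 0.4 BL s^-1 and step by 0.3 with 25-min
    increments; the open-tank feeding cycle is 40 min. The SDA kernel is
    a lagged Erlang density: digestion starts after ``sda_lag_h`` and 95%
    of the kernel mass falls within ``sda_duration_h`` thereafter, giving
    the ~50 h single-meal response reported for rainbow trout and an
    equilibrium that emerges after a few days of daily feeding.
    """

    seed: int = 0
    noise_cv: float = 0.03
    n_fish: int = 10
    speed_start: float = 0.4
    speed_step: float = 0.3
    increment_min: float = 25.0
    ucrit_mean: float = 2.0
    ucrit_sd: float = 0.25
    temperatures: tuple[float, ...] = (10.0, 15.0, 20.0)
    sda_shape: float = 4.0
    sda_lag_h: float = 6.0
    sda_duration_h: float = 50.0
    feed_cycle_s: float = 2400.0
    night_window: tuple[float, float] = (19.0, 7.0)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size=None
) -> np.ndarray | float:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def gen_swim_trials(
    config: GeneratorConfig, truth: SwimCurve
) -> pd.DataFrame:
    """Incremental-velocity trials for ``config.n_fish`` fish.

    Columns: fish_id, speed_bl_s, mo2_mg_kg_h, increment_min,
    time_in_final_min. Completed increments carry the full increment
    duration; the final row of each fish is the fatigue increment, whose
    partial time is drawn so the Brett formula recovers that fish's
    target Ucrit.
    """
    rng = config.rng()
    rows = []
    for fish in range(config.n_fish):
        target_ucrit = max(
            rng.normal(config.ucrit_mean, config.ucrit_sd),
            config.speed_start + 0.5 * config.speed_step,
        )
        speed = config.speed_start
        while True:
            completed = speed <= target_ucrit
            mo2 = mo2_at_speed(truth, speed) * _lognormal_factor(
                rng, config.noise_cv
            )
            if completed:
                t_final = config.increment_min
            else:
                # fatigue partway through this increment: Brett inversion
                t_final = (
                    (target_ucrit - (speed - config.speed_step))
                    / config.speed_step
                    * config.increment_min
                )
            rows.append(
                (fish, round(speed, 10), mo2, config.increment_min, t_final)
            )
            if not completed:
                break
            speed += config.speed_step
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id",
            "speed_bl_s",
            "mo2_mg_kg_h",
            "increment_min",
            "time_in_final_min",
        ],
    )


def gen_hypoxia_trace(
    config: GeneratorConfig,
    truth: HillParams,
    curve: SwimCurve,
    tank_volume: float,
    fish_mass: float,
    water: WaterConditions | None = None,
    speed_bl_s: float = 2.0,
    dt_s: float = 1.0,
    stop_mo2_fraction: float = 0.05,
) -> RespirometryTrace:
    """Self-induced-hypoxia O2 decline in a closed swim-tunnel.

    The fish swims at ``speed_bl_s`` while its own uptake deoxygenates
    the chamber: dO2/dt = -min(demand, ceiling(pO2)) * m / V_eff. The
    default speed is chosen so the aerobic demand sits high on the
    sigmoid (well above AMR/2) and the declining trace therefore
    traverses the inflection, which a subsequent Hill fit needs.
    Integration stops once the capped uptake collapses below
    ``stop_mo2_fraction`` of the demand — the trial's operational
    endpoint, by when the fish has long lost the swimming speed — or
    after 24 h. Sensor noise is multiplicative lognormal on the O2
    readings.
    """
    if tank_volume <= fish_mass:
        raise ValueError("tank volume must exceed fish displacement")
    if water is None:
        water = WaterConditions(
            temperature=truth.temperature if truth.temperature is not None
            else 15.0
        )
    rng = config.rng()
    demand = mo2_at_speed(curve, speed_bl_s)
    if demand >= truth.amr:
        raise ValueError(
            "aerobic demand at the chosen speed exceeds AMR; pick a speed "
            "the fish can sustain in normoxia"
        )
    v_eff = tank_volume - fish_mass
    conc = water.solubility
    times, o2 = [], []
    t = 0.0
    max_steps = int(24 * 3600 / dt_s)
    for _ in range(max_steps):
        times.append(t)
        o2.append(conc)
        po2 = conc * water.kpa_per_mgl
        mo2 = min(demand, hill_ceiling(truth, po2))
        if mo2 <= stop_mo2_fraction * demand:
            break
        conc = max(conc - mo2 * fish_mass / v_eff / 3600.0 * dt_s, 1e-9)
        t += dt_s
    o2 = np.asarray(o2)
    noisy = o2 * _lognormal_factor(rng, config.noise_cv, size=o2.shape)
    return RespirometryTrace(
        time_s=np.asarray(times),
        o2=noisy,
        phase=np.full(len(times), "measure", dtype=object),
        respirometer_volume=tank_volume,
        fish_mass=fish_mass,
        water=water,
    )


def hypoxia_points_from_trace(
    trace: RespirometryTrace,
    demand: float | None = None,
    window_s: float | None = None,
) -> pd.DataFrame:
    """Reconstruct (pO2, MO2) pairs from a hypoxia trace.

    With ``window_s`` unset, adjacent-sample forward differences are used
    (with the left-endpoint pO2 this exactly inverts the generator's
    integration scheme on a noiseless trace); with noise, a windowed
    regression of the requested span is used instead. Points whose MO2 is
    at the swimming demand (the uncapped plateau) do not lie on the Hill
    curve, so when ``demand`` is given they are dropped.
    """
    if trace.water is None:
        raise ValueError("trace carries no water conditions")
    k = trace.water.kpa_per_mgl
    t, y = trace.time_s, trace.o2
    factor = 3600.0 * trace.effective_volume / trace.fish_mass
    if window_s is None:
        slopes = np.diff(y) / np.diff(t)
        po2 = y[:-1] * k
        mo2 = -slopes * factor
    else:
        edges = np.arange(t[0], t[-1], window_s)
        po2_list, mo2_list = [], []
        for lo in edges:
            sel = (t >= lo) & (t < lo + window_s)
            if sel.sum() < 3:
                continue
            slope = np.polyfit(t[sel], y[sel], 1)[0]
            po2_list.append(y[sel].mean() * k)
            mo2_list.append(-slope * factor)
        po2, mo2 = np.asarray(po2_list), np.asarray(mo2_list)
    keep = (mo2 > 0) & (po2 > 0)
    if demand is not None:
        keep &= mo2 < 0.9 * demand
    return pd.DataFrame(
        {"po2_kpa": po2[keep], "mo2_mg_kg_h": mo2[keep]}
    )


def gen_sda_series(
    config: GeneratorConfig,
    rmr: float,
    target_fraction: float = 0.40,
    days: int = 17,
    feed_day_first: int = 2,
    feed_day_last: int = 11,
    feed_hour: float = 12.0,
    day_activity_fraction: float = 0.0,
) -> SdaSeries:
    """Open-tank feeding series: RMR plus superposed SDA meal kernels.

    Each daily meal adds a lagged-Erlang SDA response scaled so that the
    equilibrium daily-mean MO2 is ``rmr * (1 + target_fraction)``; no feed
    is given in the first 24 h. ``day_activity_fraction`` optionally adds
    a half-sine daytime activity excursion (fraction of RMR at midday),
    emulating the routine daytime restlessness that makes night
    measurements the usable RMR baseline.
    """
    if rmr <= 0:
        raise ValueError("RMR must be > 0")
    if feed_day_first < 1:
        raise ValueError("feeding cannot start before day 1")
    # an empty feeding range (last < first) yields an unfed, flat series
    rng = config.rng()
    t_h = np.arange(0.0, days * 24.0, config.feed_cycle_s / 3600.0)
    t_h = t_h + 0.5 * config.feed_cycle_s / 3600.0  # cycle midpoints
    feeds = np.array(
        [
            (d - 1) * 24.0 + feed_hour
            for d in range(feed_day_first, feed_day_last + 1)
        ]
    )
    # Erlang kernel: 95% of mass within sda_duration_h after the lag
    scale = config.sda_duration_h / gamma_dist.ppf(0.95, a=config.sda_shape)
    kernel = gamma_dist(
        a=config.sda_shape, scale=scale, loc=config.sda_lag_h
    )
    signal = np.full_like(t_h, rmr)
    amplitude = target_fraction * rmr * 24.0  # per-meal integral
    for ft in feeds:
        signal += amplitude * kernel.pdf(t_h - ft)
    if day_activity_fraction > 0:
        hod = np.mod(t_h, 24.0)
        day = (hod >= 7.0) & (hod < 19.0)
        bump = np.zeros_like(t_h)
        bump[day] = (
            day_activity_fraction
            * rmr
            * np.sin(np.pi * (hod[day] - 7.0) / 12.0)
            * rng.uniform(0.2, 1.0, size=day.sum())
        )
        signal = signal + bump
    mo2 = signal * _lognormal_factor(rng, config.noise_cv, size=t_h.shape)
    return SdaSeries(
        time_h=t_h,
        mo2=mo2,
        feeding_times_h=feeds,
        night_window=config.night_window,
    )
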