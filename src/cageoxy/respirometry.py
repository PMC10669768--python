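"""Respirometry analysis: slope-based MO2, RMR baseline, SDA equilibrium.

Intermittent-flow respirometry cycles through flush / wait / measure
phases; during a measure phase the chamber is closed and the O2 decline
is linear for a well-mixed chamber, so mass-specific oxygen uptake is

    MO2 = -slope * 3600 * V_eff / m        (mg O2 kg^-1 h^-1)

with slope in mg L^-1 s^-1 and effective volume V_eff the respirometer
volume minus the fish's displacement volume (1 kg of fish displacing 1 L).
Long open-tank series with daily feeding yield the routine metabolic rate
(RMR, median of pre-feeding night measurements) and the equilibrium SDA
plateau that daily feeding builds up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .water import WaterConditions

__all__ = [
    "RespirometryTrace",
    "SdaSeries",
    "SdaEquilibrium",
    "mo2_from_phase",
    "rmr_baseline",
    "sda_equilibrium",
    "trace_from_frame",
    "mo2_series_from_trace",
]

PHASES = ("flush", "wait", "measure")


@dataclass
class RespirometryTrace:
    """Timestamped O2 trace with phase annotations.

    o2 is in mg L^-1; ``blank_o2``, when present, is a parallel channel
    from a fish-free blank used to correct for background (microbial)
    respiration.
    """

    time_s: np.ndarray
    o2: np.ndarray
    phase: np.ndarray
    respirometer_volume: float  # L
    fish_mass: float  # kg
    blank_o2: np.ndarray | None = None
    water: "WaterConditions | None" = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time_s) == len(self.o2) == len(self.phase)):
            raise ValueError("time, o2 and phase must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        unknown = set(np.unique(self.phase)) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        if self.respirometer_volume <= self.fish_mass:
            raise ValueError(
                "respirometer volume must exceed the fish displacement "
                "volume (1 kg ~ 1 L)"
            )

    @property
    def effective_volume(self) -> float:
        """Water volume actually holding oxygen: chamber minus fish."""
        return self.respirometer_volume - self.fish_mass

    def measure_phases(self) -> list[np.ndarray]:
        """Index arrays of the contiguous measure phases, in time order."""
        is_meas = self.phase == "measure"
        edges = np.flatnonzero(np.diff(np.r_[False, is_meas, False]))
        return [
            np.arange(edges[i], edges[i + 1])
            for i in range(0, len(edges), 2)
        ]


def trace_from_frame(
    frame: pd.DataFrame,
    respirometer_volume: float,
    fish_mass: float,
) -> RespirometryTrace:
    """Build a trace from a (time_s, o2, phase[, channel]) table.

    With a ``channel`` column, rows labelled ``blank`` become the
    background channel (aligned on time) and rows labelled ``fish`` the
    animal channel.
    """
    if "channel" in frame.columns:
        fish = frame[frame["channel"] == "fish"]
        blank = frame[frame["channel"] == "blank"]
        blank_o2 = (
            blank.set_index("time_s")["o2"]
            .reindex(fish["time_s"])
            .to_numpy()
            if len(blank)
            else None
        )
        frame = fish
    else:
        blank_o2 = None
    return RespirometryTrace(
        time_s=frame["time_s"].to_numpy(),
        o2=frame["o2"].to_numpy(),
        phase=frame["phase"].to_numpy(),
        respirometer_volume=respirometer_volume,
        fish_mass=fish_mass,
        blank_o2=blank_o2,
    )


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    return float(np.polyfit(t, y, 1)[0])


def mo2_from_phase(
    trace: RespirometryTrace,
    phase_index: int,
    subtract_blank: bool = False,
) -> float:
    """Mass-specific MO2 from the ``phase_index``-th measure phase.

    A blank-channel slope is subtracted when requested (background
    respiration is typically negligible in a cleaned system, so the
    correction defaults off). A negative result (O2 rising) raises.
    """
    phases = trace.measure_phases()
    if not 0 <= phase_index < len(phases):
        raise IndexError(
            f"measure phase {phase_index} out of range "
            f"(trace has {len(phases)})"
        )
    idx = phases[phase_index]
    if len(idx) < 2:
        raise ValueError("a measure phase needs at least 2 samples")
    t = trace.time_s[idx]
    slope = _slope(t, trace.o2[idx])
    if subtract_blank:
        if trace.blank_o2 is None:
            raise ValueError("trace has no blank channel")
        slope -= _slope(t, trace.blank_o2[idx])
    mo2 = -slope * 3600.0 * trace.effective_volume / trace.fish_mass
    if mo2 < 0:
        raise ValueError(
            f"negative MO2 ({mo2:.3g}) in measure phase {phase_index}: "
            "O2 increased during the closed phase"
        )
    return mo2


def mo2_series_from_trace(
    trace: RespirometryTrace, subtract_blank: bool = False
) -> pd.DataFrame:
    """MO2 for every measure phase: columns (time_s, mo2_mg_kg_h)."""
    rows = []
    for i, idx in enumerate(trace.measure_phases()):
        rows.append(
            (
                float(trace.time_s[idx].mean()),
                mo2_from_phase(trace, i, subtract_blank),
            )
        )
    return pd.DataFrame(rows, columns=["time_s", "mo2_mg_kg_h"])


@dataclass
class SdaSeries:
    """Cycle-level MO2 series from a long feeding experiment.

    time_h counts from the start of the experiment; feeding_times_h mark
    meal onsets; the night window is a clock-hour interval (start, end)
    wrapping midnight, defaulting to 19:00-07:00 for a 12:12 photoperiod.
    Experiment start is taken as midnight of day 1.
    """

    time_h: np.ndarray
    mo2: np.ndarray
    feeding_times_h: np.ndarray = field(
        default_factory=lambda: np.array([])
    )
    ration_fraction: float = 0.01
    night_window: tuple[float, float] = (19.0, 7.0)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.mo2 = np.asarray(self.mo2, dtype=float)
        self.feeding_times_h = np.asarray(self.feeding_times_h, dtype=float)
        if len(self.time_h) != len(self.mo2):
            raise ValueError("time and MO2 must have equal length")
        if np.any(self.mo2 < 0):
            raise ValueError("MO2 must be >= 0")
        if self.ration_fraction < 0:
            raise ValueError("ration must be >= 0")

    def is_night(self, time_h: np.ndarray) -> np.ndarray:
        hod = np.mod(time_h, 24.0)
        start, end = self.night_window
        if start <= end:
            return (hod >= start) & (hod < end)
        return (hod >= start) | (hod < end)

    def daily_means(self) -> pd.Series:
        """Mean MO2 per complete experiment day (day 1 = first 24 h)."""
        day = np.floor(self.time_h / 24.0).astype(int) + 1
        full = pd.Series(self.mo2).groupby(day).mean()
        # drop a trailing partial day
        last_day = int(np.floor(self.time_h.max() / 24.0)) + 1
        if self.time_h.max() % 24.0 < 23.0 and last_day in full.index:
            full = full.drop(last_day)
        return full


def rmr_baseline(series: SdaSeries) -> float:
    """Routine metabolic rate: median of pre-feeding night measurements."""
    mask = series.is_night(series.time_h)
    if series.feeding_times_h.size:
        mask &= series.time_h < series.feeding_times_h.min()
    if not mask.any():
        raise ValueError(
            "no night-time measurements precede the first feeding"
        )
    return float(np.median(series.mo2[mask]))


@dataclass(frozen=True)
class SdaEquilibrium:
    """SDA plateau summary: level, rise over RMR, and onset day."""

    equilibrium_mo2: float | None
    percent_increase: float | None
    onset_day: int | None

    @property
    def reached(self) -> bool:
        return self.equilibrium_mo2 is not None


def sda_equilibrium(
    series: SdaSeries,
    rmr: float,
    window_days: int = 3,
    tol: float = 0.05,
) -> SdaEquilibrium:
    """Detect the SDA equilibrium plateau under regular feeding.

    Daily-mean MO2 values are scanned for the first run of at least
    ``window_days`` consecutive days whose means agree pairwise within
    ``tol`` (relative); the run is extended while agreement holds. The
    plateau is the mean over that run.
    """
    if not series.feeding_times_h.size:
        raise ValueError("series has no feeding events")
    if rmr <= 0:
        raise ValueError("RMR must be > 0")
    daily = series.daily_means()
    days = daily.index.to_numpy()
    vals = daily.to_numpy()

    def close(block: np.ndarray) -> bool:
        return (block.max() - block.min()) <= tol * block.mean()

    n = len(vals)
    for start in range(0, n - window_days + 1):
        # runs must be consecutive calendar days
        if days[start + window_days - 1] - days[start] != window_days - 1:
            continue
        end = start + window_days
        if not close(vals[start:end]):
            continue
        while (
            end < n
            and days[end] - days[end - 1] == 1
            and close(vals[start : end + 1])
        ):
            end += 1
        eq = float(vals[start:end].mean())
        return SdaEquilibrium(
            equilibrium_mo2=eq,
            percent_increase=100.0 * (eq - rmr) / rmr,
            onset_day=int(days[start]),
        )
    return SdaEquilibrium(None, None, None)
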