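"""Piecewise-constant time-temperature trajectories.

A :class:`TemperatureProfile` is the canonical container for logger data in a
cold chain: ``n + 1`` breakpoints (days) delimit ``n`` segments, each held at a
constant temperature.  Uniformly sampled logger streams (one reading every
``sampling_interval_s`` seconds) are a special case built with
:meth:`TemperatureProfile.from_readings`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440.0
SECONDS_PER_DAY = 86400.0


def minutes_to_days(minutes: float, ndigits: int | None = None) -> float:
    """Convert minutes to days (1 d = 1,440 min), optionally rounding."""
    days = minutes / MINUTES_PER_DAY
    return round(days, ndigits) if ndigits is not None else days


def days_to_minutes(days: float) -> float:
    return days * MINUTES_PER_DAY


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant temperature trajectory.

    Parameters
    ----------
    breakpoints
        Strictly increasing segment boundaries in days; length ``n + 1``.
    temperatures
        Temperature (deg C) held over each of the ``n`` segments.
    sampling_interval_s
        Metadata: the logger sampling interval behind the segments, seconds.
    """

    breakpoints: tuple[float, ...]
    temperatures: tuple[float, ...]
    sampling_interval_s: float = 30.0
    stage: str = ""
    sensor_id: str = ""

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        tv = np.asarray(self.temperatures, dtype=float)
        if bp.ndim != 1 or bp.size < 2:
            raise ValueError("profile needs at least two breakpoints")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if tv.size != bp.size - 1:
            raise ValueError(
                f"need one temperature per segment: {tv.size} temperatures "
                f"for {bp.size - 1} segments"
            )
        if not np.all(np.isfinite(tv)):
            raise ValueError("temperatures must be finite")
        object.__setattr__(self, "breakpoints", tuple(bp.tolist()))
        object.__setattr__(self, "temperatures", tuple(tv.tolist()))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_readings(
        cls,
        temps_c,
        interval_s: float = 30.0,
        t0_d: float = 0.0,
        stage: str = "",
        sensor_id: str = "",
    ) -> "TemperatureProfile":
        """Build a uniform profile from a logger reading series."""
        temps = np.asarray(list(temps_c), dtype=float)
        if temps.size == 0:
            raise ValueError("empty reading series")
        dt_d = interval_s / SECONDS_PER_DAY
        bp = t0_d + dt_d * np.arange(temps.size + 1)
        return cls(tuple(bp), tuple(temps), interval_s, stage, sensor_id)

    @classmethod
    def from_segments(cls, segments, sampling_interval_s: float = 30.0) -> "TemperatureProfile":
        """Build from ``[(temperature_C, duration_d), ...]`` pairs."""
        temps, bp, t = [], [0.0], 0.0
        for temp_c, dur_d in segments:
            if dur_d <= 0:
                raise ValueError("segment durations must be positive")
            t += float(dur_d)
            bp.append(t)
            temps.append(float(temp_c))
        if not temps:
            raise ValueError("no segments given")
        return cls(tuple(bp), tuple(temps), sampling_interval_s)

    # -- views -------------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.temperatures)

    @property
    def durations_d(self) -> np.ndarray:
        return np.diff(np.asarray(self.breakpoints))

    @property
    def total_duration_d(self) -> float:
        return self.breakpoints[-1] - self.breakpoints[0]

    @property
    def start_times_min(self) -> np.ndarray:
        return np.asarray(self.breakpoints[:-1]) * MINUTES_PER_DAY

    def temperature_at(self, t_d: float) -> float:
        """Temperature of the segment containing time ``t_d`` (days)."""
        bp = np.asarray(self.breakpoints)
        if not (bp[0] <= t_d <= bp[-1]):
            raise ValueError(f"time {t_d} d outside profile span")
        i = min(int(np.searchsorted(bp, t_d, side="right")) - 1, self.n_segments - 1)
        return self.temperatures[i]

    def stats(self) -> dict:
        """Exact extrema, arithmetic mean and reading count of the segments."""
        return profile_stats(self.temperatures)

    # -- round-trippable CSV I/O ------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_min": np.asarray(self.breakpoints[:-1]) * MINUTES_PER_DAY,
                "temp_C": self.temperatures,
                "stage": self.stage,
                "sensor_id": self.sensor_id,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sampling_interval_s: float | None = None) -> "TemperatureProfile":
        """Read a ``timestamp_min,temp_C[,stage,sensor_id]`` log.

        Each row is a reading taken at ``timestamp_min``; the final reading is
        held for one sampling interval (inferred from the median spacing when
        not given).
        """
        df = pd.read_csv(path)
        for col in ("timestamp_min", "temp_C"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column '{col}'")
        t_min = df["timestamp_min"].to_numpy(dtype=float)
        temps = df["temp_C"].to_numpy(dtype=float)
        if t_min.size == 0:
            raise ValueError(f"{path}: empty temperature log")
        if np.any(np.diff(t_min) <= 0) and t_min.size > 1:
            raise ValueError(f"{path}: timestamps must be strictly increasing")
        if sampling_interval_s is None:
            if t_min.size > 1:
                sampling_interval_s = float(np.median(np.diff(t_min)) * 60.0)
            else:
                sampling_interval_s = 30.0
        tail_d = sampling_interval_s / SECONDS_PER_DAY
        bp = np.append(t_min / MINUTES_PER_DAY, t_min[-1] / MINUTES_PER_DAY + tail_d)
        stage = str(df["stage"].iloc[0]) if "stage" in df.columns else ""
        sensor = str(df["sensor_id"].iloc[0]) if "sensor_id" in df.columns else ""
        return cls(tuple(bp), tuple(temps), sampling_interval_s, stage, sensor)

    def resample(self, interval_s: float) -> "TemperatureProfile":
        """Re-express the trajectory as uniform readings at ``interval_s``."""
        if interval_s <= 0:
            raise ValueError("interval must be positive")
        dt_d = interval_s / SECONDS_PER_DAY
        t = np.arange(self.breakpoints[0], self.breakpoints[-1], dt_d)
        temps = [self.temperature_at(ti) for ti in t]
        return TemperatureProfile.from_readings(
            temps, interval_s, t0_d=self.breakpoints[0], stage=self.stage, sensor_id=self.sensor_id
        )


def profile_stats(readings) -> dict:
    """Exact ``{min, max, mean, count}`` of a temperature reading series."""
    arr = np.asarray(list(readings), dtype=float)
    if arr.size == 0:
        raise ValueError("empty reading series")
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "count": int(arr.size),
    }
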