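"""Quality decay, five-band classification and TTT shelf-life accounting.

The quality index is dimensionless on [0, 1] and is calibrated by anchor
points (time, quality); between and beyond the anchors the curve is
piecewise-linear (linearly extrapolated, clamped to [0, 1]).  Quality is cut
into five equal bands; band boundaries belong to the upper band.

Shelf life under a temperature history follows the time-temperature-tolerance
(TTT) principle: each segment of duration dt at temperature T consumes
dt / SL(T) of the product's shelf life, where SL(T) is a reference shelf-life
table interpolated in temperature.  Total remaining life at the end of the
chain is the residual SL at the terminal holding temperature, so the
predicted expiration horizon is elapsed + residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np
import pandas as pd

from .profiles import TemperatureProfile

#: Five equal quality bands, numbered 1 (worst) to 5 (best).
QUALITY_BANDS = (
    (1, 0.0, 0.2, "worst quality"),
    (2, 0.2, 0.4, "safe reference"),
    (3, 0.4, 0.6, "fair quality"),
    (4, 0.6, 0.8, "good quality"),
    (5, 0.8, 1.0, "better quality"),
)


@dataclass(frozen=True)
class QualityModel:
    """Quality-decay calibration and shelf-life reference table.

    anchors
        (time_d, quality) calibration points, strictly decreasing in quality.
    sl_reference
        Map temperature (degC) -> shelf life (d); linearly interpolated
        between tabulated temperatures, never extrapolated.
    safe_band
        Index of the band taken as the safety reference (default 2, the
        0.2-0.4 band).
    arrhenius
        Optional (sl_ref_d, t_ref_C, k) triple switching SL(T) to the
        exponential form SL = sl_ref * exp(-k (T - t_ref)); off by default.
    """

    anchors: tuple[tuple[float, float], ...]
    sl_reference: tuple[tuple[float, float], ...] = ()
    safe_band: int = 2
    arrhenius: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least two quality anchors")
        anchors = tuple(sorted((float(t), float(q)) for t, q in self.anchors))
        times = [t for t, _ in anchors]
        quals = [q for _, q in anchors]
        if len(set(times)) != len(times):
            raise ValueError("anchor times must be distinct")
        if any(q1 <= q2 for q1, q2 in zip(quals, quals[1:])):
            raise ValueError("anchor quality must strictly decrease over time")
        if any(not 0 <= q <= 1 for q in quals):
            raise ValueError("anchor quality must lie in [0, 1]")
        sl = tuple(sorted((float(T), float(d)) for T, d in self.sl_reference))
        if any(d <= 0 for _, d in sl):
            raise ValueError("reference shelf lives must be positive")
        object.__setattr__(self, "anchors", anchors)
        object.__setattr__(self, "sl_reference", sl)

    # -- shelf-life reference ---------------------------------------------

    def shelf_life_at(self, T: float) -> float:
        """Reference shelf life (d) at temperature T (degC)."""
        if self.arrhenius is not None:
            sl_ref, t_ref, k = self.arrhenius
            return sl_ref * exp(-k * (T - t_ref))
        if not self.sl_reference:
            raise ValueError("no shelf-life reference table configured")
        temps = np.array([t for t, _ in self.sl_reference])
        sls = np.array([d for _, d in self.sl_reference])
        if not (temps[0] <= T <= temps[-1]):
            raise ValueError(
                f"temperature {T} degC outside the shelf-life table range "
                f"[{temps[0]}, {temps[-1]}]"
            )
        return float(np.interp(T, temps, sls))


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """Composed shelf-life prediction for one batch."""

    elapsed_d: float
    residual_d: float
    ttt_fraction: float = 0.0

    @property
    def total_d(self) -> float:
        return self.elapsed_d + self.residual_d

    @property
    def expired(self) -> bool:
        return self.ttt_fraction >= 1.0

    def to_dict(self) -> dict:
        return {
            "elapsed_d": self.elapsed_d,
            "residual_d": self.residual_d,
            "total_d": self.total_d,
            "ttt_fraction": self.ttt_fraction,
            "expired": self.expired,
        }


def _line(qm: QualityModel):
    times = np.array([t for t, _ in qm.anchors])
    quals = np.array([q for _, q in qm.anchors])
    return times, quals


def quality_at(t: float, qm: QualityModel) -> float:
    """Quality index at time t (d): piecewise-linear through the anchors,
    linearly extrapolated beyond them with the end segments, clamped to
    [0, 1]."""
    if t < 0:
        raise ValueError("time must be >= 0")
    times, quals = _line(qm)
    if t <= times[0]:
        slope = (quals[1] - quals[0]) / (times[1] - times[0])
        q = quals[0] + slope * (t - times[0])
    elif t >= times[-1]:
        slope = (quals[-1] - quals[-2]) / (times[-1] - times[-2])
        q = quals[-1] + slope * (t - times[-1])
    else:
        q = float(np.interp(t, times, quals))
    return float(min(1.0, max(0.0, q)))


def classify_quality(q: float) -> tuple[int, str]:
    """Band (1-5) containing quality q; boundaries belong to the upper band."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quality {q} outside [0, 1]")
    for idx, lo, hi, label in reversed(QUALITY_BANDS):
        if q >= lo:
            return idx, label
    return 1, QUALITY_BANDS[0][3]  # pragma: no cover - q >= 0 always matches


def time_to_quality(q_target: float, qm: QualityModel) -> float:
    """Inverse of :func:`quality_at`: first time (d) at which the decay curve
    reaches ``q_target``.  Exact for the piecewise-linear calibration."""
    times, quals = _line(qm)
    q0 = quality_at(0.0, qm)
    if q_target > q0 or q_target < 0:
        raise ValueError(
            f"quality {q_target} is unreachable (curve spans [0, {q0}] for t >= 0)"
        )
    # walk segments (including the extrapolated tails) for the crossing
    if q_target >= quals[0]:
        slope = (quals[1] - quals[0]) / (times[1] - times[0])
        return float(times[0] + (q_target - quals[0]) / slope)
    for i in range(len(times) - 1):
        if quals[i + 1] <= q_target <= quals[i]:
            slope = (quals[i + 1] - quals[i]) / (times[i + 1] - times[i])
            return float(times[i] + (q_target - quals[i]) / slope)
    slope = (quals[-1] - quals[-2]) / (times[-1] - times[-2])
    return float(times[-1] + (q_target - quals[-1]) / slope)


def ttt_consumed(profile: TemperatureProfile | None, qm: QualityModel) -> float:
    """Cumulative fraction of shelf life consumed over a temperature history:
    sum over segments of dt_i / SL(T_i).  Additive over concatenated
    profiles; 0 for an empty history."""
    if profile is None or profile.n_segments == 0:
        return 0.0
    total = 0.0
    for i, (dt, T) in enumerate(zip(profile.durations_d, profile.temperatures)):
        try:
            sl = qm.shelf_life_at(T)
        except ValueError as err:
            raise ValueError(f"segment {i} ({T} degC): {err}") from err
        total += dt / sl
    return float(total)


def compose_shelf_life(elapsed_d: float, terminal_T: float, qm: QualityModel,
                       profile: TemperatureProfile | None = None) -> ShelfLifeEstimate:
    """Total shelf-life prediction: time already spent in the chain plus the
    residual reference shelf life at the terminal holding temperature.

    When the full temperature history is supplied, the TTT fraction consumed
    is reported alongside (and flags expiry at >= 1)."""
    if elapsed_d < 0:
        raise ValueError("elapsed time must be >= 0")
    residual = qm.shelf_life_at(terminal_T)
    fraction = ttt_consumed(profile, qm) if profile is not None else 0.0
    return ShelfLifeEstimate(elapsed_d=elapsed_d, residual_d=residual,
                             ttt_fraction=fraction)


def shelf_life_report(estimates: dict[str, ShelfLifeEstimate]) -> pd.DataFrame:
    """Tabular per-batch report: elapsed, residual, total, TTT fraction and
    quality band at the elapsed time is left to the caller's quality model."""
    rows = [{"batch": k, **v.to_dict()} for k, v in estimates.items()]
    return pd.DataFrame(rows)
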