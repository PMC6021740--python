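"""Safety decision layer: HACCP time gate, temperature-excursion detection,
and the examine -> warn -> regulate -> re-examine loop.

Decisions are records, not side effects: each carries its target (operation
protocol or quality assessment), the object it judged, the method label
(HACCP, GMP, TTT, quality model) and an outcome payload with a boolean
``safe`` flag.  The engine-facing guard for the HACCP gate is registered so
Petri-net transitions can be gated on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .petri import Token, register_guard
from .profiles import MINUTES_PER_DAY, TemperatureProfile

ALLOWED_METHODS = ("HACCP", "GMP", "TTT", "quality model")


@dataclass(frozen=True)
class Decision:
    target: str                  # "operation protocol" | "quality assessment"
    object: str
    method: str
    result: dict
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ALLOWED_METHODS:
            raise ValueError(f"method must be one of {ALLOWED_METHODS}")
        if "safe" not in self.result or not isinstance(self.result["safe"], bool):
            raise ValueError("decision result must carry a boolean 'safe' flag")

    @property
    def safe(self) -> bool:
        return self.result["safe"]


@dataclass(frozen=True)
class ExcursionEvent:
    """A maximal run of readings beyond a temperature bound."""

    start_min: float
    end_min: float
    peak_deviation_c: float      # degC beyond the violated bound, > 0
    bound_violated: str          # "upper" | "lower"

    def __post_init__(self) -> None:
        if self.end_min <= self.start_min:
            raise ValueError("event end must follow its start")
        if self.peak_deviation_c <= 0:
            raise ValueError("peak deviation must be positive")

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


def haccp_time_gate(t_start_min: float, t_end_min: float,
                    limit_min: float = 40.0) -> Decision:
    """Critical-control-point gate on a processing duration.

    Safe iff t_end - t_start <= limit (inclusive, the default limit being the
    40-min fresh-product bound).  A safe outcome enables the successor step;
    an unsafe one demands a quality analysis instead.
    """
    if limit_min <= 0:
        raise ValueError("limit must be positive")
    duration = t_end_min - t_start_min
    if duration < 0:
        raise ValueError("negative processing duration")
    safe = duration <= limit_min
    return Decision(
        target="operation protocol",
        object=f"processing duration {duration:g} min",
        method="HACCP",
        result={
            "safe": safe,
            "duration_min": duration,
            "limit_min": limit_min,
            "enable_next": safe,
            "quality_analysis_required": not safe,
        },
        timestamp_min=t_end_min,
    )


def haccp_guard(limit_min: float = 40.0):
    """Guard predicate over consumed tokens for Petri-net transitions: passes
    when every token whose content carries t_start_min/t_end_min satisfies
    the time gate."""

    def guard(tokens: list[Token]) -> bool:
        for tok in tokens:
            c = tok.content_dict
            if "t_start_min" in c and "t_end_min" in c:
                d = haccp_time_gate(c["t_start_min"], c["t_end_min"], limit_min)
                if not d.safe:
                    return False
        return True

    return guard


register_guard("haccp_40min", haccp_guard(40.0))


def detect_excursions(profile: TemperatureProfile, lower: float,
                      upper: float) -> list[ExcursionEvent]:
    """Maximal runs of consecutive readings outside [lower, upper].

    Readings exactly at a bound are compliant.  A run is split when the
    violated bound changes side.  Events are returned in start order.
    """
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    bp = np.asarray(profile.breakpoints)
    temps = np.asarray(profile.temperatures)
    events: list[ExcursionEvent] = []
    run_start = None
    run_side = None
    run_peak = 0.0
    for i, T in enumerate(temps):
        side = "upper" if T > upper else ("lower" if T < lower else None)
        if side is None or side != run_side:
            if run_side is not None:
                events.append(ExcursionEvent(
                    start_min=run_start, end_min=bp[i] * MINUTES_PER_DAY,
                    peak_deviation_c=run_peak, bound_violated=run_side))
            run_side, run_start, run_peak = side, bp[i] * MINUTES_PER_DAY, 0.0
        if side is not None:
            dev = T - upper if side == "upper" else lower - T
            run_peak = max(run_peak, dev)
    if run_side is not None:
        events.append(ExcursionEvent(
            start_min=run_start, end_min=bp[-1] * MINUTES_PER_DAY,
            peak_deviation_c=run_peak, bound_violated=run_side))
    return events


def regulation_loop(profile: TemperatureProfile, lower: float, upper: float,
                    pull_rate_c_per_min: float) -> tuple[TemperatureProfile, list[Decision]]:
    """Simulate the examine -> warn -> regulate -> re-examine cycle.

    When a reading breaches a bound, a warning decision is recorded and the
    regulation mechanism takes control: the temperature is pulled linearly
    from the onset value toward the violated bound at ``pull_rate_c_per_min``
    and then held at the bound while the uncontrolled readings stay out of
    range.  The cycle releases as soon as the underlying reading is compliant
    again (or breaches the opposite bound, which starts a fresh cycle).  One
    decision per cycle; pull_rate > 0 guarantees termination.
    """
    if pull_rate_c_per_min <= 0:
        raise ValueError("pull rate must be positive")
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    bp = np.asarray(profile.breakpoints)
    t_min = bp[:-1] * MINUTES_PER_DAY
    temps = list(profile.temperatures)
    decisions: list[Decision] = []
    regulated = list(temps)
    cycle = None  # (onset_min, onset_temp, side)
    for i, T in enumerate(temps):
        side_now = "upper" if T > upper else ("lower" if T < lower else None)
        if cycle is not None:
            onset_min, onset_T, side = cycle
            if side_now == side:
                dt = t_min[i] - onset_min
                if side == "upper":
                    regulated[i] = max(upper, onset_T - pull_rate_c_per_min * dt)
                else:
                    regulated[i] = min(lower, onset_T + pull_rate_c_per_min * dt)
                continue
            cycle = None  # reading back in range (or flipped side): release
        if side_now is None:
            regulated[i] = T
            continue
        side = side_now
        bound = upper if side == "upper" else lower
        dev = abs(T - bound)
        decisions.append(Decision(
            target="operation protocol",
            object=f"temperature excursion {T:g} degC beyond {side} bound {bound:g} degC",
            method="GMP",
            result={
                "safe": False,
                "bound_violated": side,
                "deviation_c": dev,
                "pull_rate_c_per_min": pull_rate_c_per_min,
                "time_to_compliance_min": dev / pull_rate_c_per_min,
            },
            timestamp_min=float(t_min[i]),
        ))
        cycle = (t_min[i], T, side)
        regulated[i] = T
    out = TemperatureProfile(
        profile.breakpoints, tuple(regulated), profile.sampling_interval_s,
        profile.stage, profile.sensor_id)
    return out, decisions


def decision_log_frame(decisions: list[Decision]) -> pd.DataFrame:
    rows = [
        {
            "timestamp_min": d.timestamp_min,
            "target": d.target,
            "object": d.object,
            "method": d.method,
            "safe": d.safe,
            "note": ";".join(f"{k}={v}" for k, v in d.result.items() if k != "safe"),
        }
        for d in decisions
    ]
    return pd.DataFrame(rows, columns=["timestamp_min", "target", "object",
                                       "method", "safe", "note"])
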