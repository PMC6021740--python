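"""Microbial growth kinetics for cold-chain spoilage organisms.

Primary model
    Baranyi-Roberts in log-count space.  The lag phase is encoded by the
    adjustment function

        F(t) = t + (1/v) * ln(exp(-v t) + exp(-h0) - exp(-v t - h0)),

    with curvature rate ``v`` (conventionally v = mu_max) and dimensionless
    initial physiological state ``h0`` (h0 = mu_max * lag).  The log count is

        y(t) = y0 + mu * F(t) - ln(1 + (exp(mu F(t)) - 1) * exp(-(ymax - y0))),

    computed in natural-log units internally; the interface speaks
    log10 CFU/g, the unit predictive microbiology reports.

Secondary model
    Ratkowsky square-root: sqrt(mu_max) = b * (T - Tmin), zero below the
    notional minimum growth temperature Tmin.

Fluctuating temperature
    A piecewise recursion: each constant-temperature segment advances the
    count with the primary model, seeded at the segment-start count, with
    mu from the secondary model at that segment's temperature.  h0 is held
    constant across segments, so the recursion re-applies lag per segment;
    it is split-invariant only in the lag-free case h0 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import TemperatureProfile

LN10 = np.log(10.0)


@dataclass(frozen=True)
class BaranyiParams:
    """Kinetic parameter set.

    y0, nmax : log10 CFU/g — initial and maximum log counts.
    mu_max   : 1/d — maximum specific growth rate (natural-log basis); leave
               None to derive it from temperature via (b, t_min).
    b, t_min : square-root secondary-model coefficient (1/(sqrt(d) degC)) and
               minimum growth temperature (degC).
    v        : 1/d — curvature rate; None means the v = mu_max convention.
    h0       : dimensionless initial physiological state (0 = no lag).
    """

    y0: float
    nmax: float
    mu_max: float | None = None
    b: float | None = None
    t_min: float | None = None
    v: float | None = None
    h0: float = 0.0

    def __post_init__(self) -> None:
        if not self.nmax > self.y0:
            raise ValueError(f"nmax ({self.nmax}) must exceed y0 ({self.y0})")
        if self.mu_max is not None and self.mu_max < 0:
            raise ValueError("mu_max must be >= 0")
        if self.mu_max is None and (self.b is None or self.t_min is None):
            raise ValueError("provide mu_max, or (b, t_min) to derive it from temperature")
        if self.v is not None and self.v <= 0:
            raise ValueError("v must be > 0")
        if self.h0 < 0:
            raise ValueError("h0 must be >= 0")


@dataclass(frozen=True)
class GrowthCurve:
    """Simulated log-count trajectory with the per-segment rates used."""

    times: tuple[float, ...]          # d
    log_counts: tuple[float, ...]     # log10 CFU/g
    mu_values: tuple[float, ...]      # 1/d, one per segment

    def to_frame(self):
        import pandas as pd

        mu = list(self.mu_values) + [np.nan] * (len(self.times) - len(self.mu_values))
        return pd.DataFrame({"time_d": self.times, "log_count": self.log_counts, "mu": mu})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def adjustment_F(t, v: float, h0: float):
    """Baranyi adjusted time F(t); the lag-delayed clock.

    F(0) = 0, F is monotone increasing, F(t) <= t, and for large t it tracks
    the asymptote t - h0/v.  h0 = 0 collapses the lag: F(t) = t exactly.
    """
    if v <= 0:
        raise ValueError("v must be > 0")
    if h0 < 0:
        raise ValueError("h0 must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if h0 == 0:
        return t_arr if t_arr.ndim else float(t_arr)
    # ln(e^{-vt} + e^{-h0} - e^{-vt-h0}) computed stably: factor e^{-h0} out of
    # the tail so large v*t cannot underflow the whole argument.
    vt = v * t_arr
    arg = np.exp(-vt) + np.exp(-h0) * (1.0 - np.exp(-vt))
    out = np.where(t_arr == 0.0, 0.0, t_arr + np.log(arg) / v)
    return out if out.ndim else float(out)


def _log_term(a, d):
    """ln(1 + (e^a - 1) e^{-d}) = ln(1 - e^{-d} + e^{a-d}), overflow-safe."""
    a = np.asarray(a, dtype=float)
    m = np.maximum(0.0, a - d)
    return m + np.log(np.exp(-m) - np.exp(-d - m) + np.exp(a - d - m))


def baranyi_log_count(t, p: BaranyiParams, sign: str = "corrected"):
    """Log count y(t) (log10 CFU/g) at constant temperature.

    ``sign="corrected"`` uses the standard saturation term exp(-(ymax - y0)),
    under which y(0) = y0, y is non-decreasing and y -> nmax.  The
    ``"as-printed"`` variant with exp(+(ymax - y0)) is exposed for comparison
    only; it is not a growth model (it drives y below y0).
    """
    mu = p.mu_max
    if mu is None:
        raise ValueError("constant-temperature evaluation needs mu_max")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    y0n, ymaxn = p.y0 * LN10, p.nmax * LN10
    v = p.v if p.v is not None else (mu if mu > 0 else 1.0)
    f = np.asarray(adjustment_F(t_arr, v, p.h0), dtype=float)
    a = mu * f
    d = ymaxn - y0n
    if sign == "corrected":
        yn = y0n + a - _log_term(a, d)
    elif sign == "as-printed":
        yn = y0n + a - np.log1p(np.expm1(np.minimum(a, 700.0)) * np.exp(min(d, 700.0)))
    else:
        raise ValueError(f"unknown sign variant {sign!r}")
    out = yn / LN10
    return out if np.ndim(t) else float(out)


def mu_from_temperature(T, b: float, t_min: float, form: str = "sqrt"):
    """Secondary model: maximum specific growth rate (1/d) at temperature T.

    Default is the Ratkowsky square-root form mu = (b (T - Tmin))^2; the
    literal linear form mu = b (T - Tmin) is available via ``form="linear"``.
    Below Tmin the rate clamps to 0 with a warning.
    """
    T_arr = np.asarray(T, dtype=float)
    delta = T_arr - t_min
    if np.any(delta < 0):
        warnings.warn(
            f"temperature below Tmin={t_min} degC: growth rate clamped to 0",
            stacklevel=2,
        )
    delta = np.maximum(delta, 0.0)
    if form == "sqrt":
        mu = (b * delta) ** 2
    elif form == "linear":
        mu = b * delta
    else:
        raise ValueError(f"unknown secondary-model form {form!r}")
    return mu if np.ndim(T) else float(mu)


def _segment_step(y_prev_ln: float, mu: float, dt: float, v: float | None,
                  h0: float, ymax_ln: float) -> float:
    """One recursion step in natural-log units from segment-start count."""
    if mu <= 0 or dt <= 0:
        return y_prev_ln
    v_eff = v if v is not None else mu
    f = adjustment_F(dt, v_eff, h0)
    a = mu * f
    d = ymax_ln - y_prev_ln
    return y_prev_ln + a - float(_log_term(a, d))


def simulate_fluctuating(profile: TemperatureProfile, p: BaranyiParams,
                         form: str = "sqrt") -> GrowthCurve:
    """Dynamic growth prediction under a fluctuating temperature profile.

    Per segment i, mu_i comes from the secondary model at that segment's
    temperature, and the primary-model increment is applied over the segment
    duration starting from the segment-start count N_{i-1}.  The curve is
    continuous at breakpoints and never exceeds nmax.
    """
    if profile.n_segments == 0:
        raise ValueError("empty temperature profile")
    if p.b is None or p.t_min is None:
        if p.mu_max is None:
            raise ValueError("params need (b, t_min) or mu_max")
        mus = np.full(profile.n_segments, p.mu_max, dtype=float)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mus = np.asarray(
                [mu_from_temperature(T, p.b, p.t_min, form=form) for T in profile.temperatures]
            )
    y_ln = p.y0 * LN10
    ymax_ln = p.nmax * LN10
    times = [profile.breakpoints[0]]
    counts = [p.y0]
    for i, dt in enumerate(profile.durations_d):
        y_ln = _segment_step(y_ln, float(mus[i]), float(dt), p.v, p.h0, ymax_ln)
        times.append(profile.breakpoints[i + 1])
        counts.append(y_ln / LN10)
    return GrowthCurve(tuple(times), tuple(counts), tuple(mus.tolist()))


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def fit_baranyi(times, log_counts, p0: BaranyiParams | None = None) -> BaranyiParams:
    """Least-squares fit of (y0, nmax, mu_max, h0) to a constant-temperature
    log-count curve, under the v = mu_max convention.

    Intended for parameter recovery on simulated curves and for users with
    their own count data; returns a new :class:`BaranyiParams`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(log_counts, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need >= 4 matched (time, log-count) points")
    if p0 is None:
        p0 = BaranyiParams(y0=float(y.min()), nmax=float(y.max()) + 0.5,
                           mu_max=1.0, h0=1.0)

    def resid(theta):
        y0, nmax, mu, h0 = theta
        if nmax <= y0:
            return np.full_like(y, 1e6)
        p = BaranyiParams(y0=y0, nmax=nmax, mu_max=mu, h0=h0)
        return baranyi_log_count(t, p) - y

    x0 = [p0.y0, p0.nmax, p0.mu_max or 1.0, p0.h0]
    sol = least_squares(
        resid, x0,
        bounds=([-10, -10, 1e-8, 0.0], [15, 15, 100, 50]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    y0, nmax, mu, h0 = sol.x
    return BaranyiParams(y0=float(y0), nmax=float(nmax), mu_max=float(mu), h0=float(h0))
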