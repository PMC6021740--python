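"""Synthetic time-temperature profile generation.

Emulates the logger streams a cold chain produces: piecewise-constant stage
plateaus with small reading noise, plus optional excursion spikes (door
openings, handover delays) of configurable magnitude and duration.  Profiles
are reproducible given the seed, and injected excursions are recoverable by
:func:`coldchain.decisions.detect_excursions` when the bounds leave margin
above the noise floor (a round-trip the test suite relies on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import SECONDS_PER_DAY, TemperatureProfile


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Recipe for a synthetic logger stream.

    stages
        (mean_C, duration_d) per chain stage, e.g. processing at 4 degC for
        0.02 d, transport at -3 degC for 0.5 d, storage at -18 degC for 10 d.
    noise_sd_c
        Reading noise, degC (default 0.3, the jitter scale of the embedded
        logger grids).
    n_excursions, excursion_magnitude_c, excursion_duration_min
        Count, height above the local stage mean and length of injected
        warm spikes.
    sampling_interval_s
        Logger cadence (default 30 s).
    """

    stages: tuple[tuple[float, float], ...]
    noise_sd_c: float = 0.3
    n_excursions: int = 0
    excursion_magnitude_c: float = 10.0
    excursion_duration_min: float = 5.0
    sampling_interval_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("need at least one stage")
        if any(d <= 0 for _, d in self.stages):
            raise ValueError("stage durations must be positive")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        if self.n_excursions < 0 or self.excursion_duration_min <= 0:
            raise ValueError("invalid excursion settings")


def generate_profile(spec: SyntheticProfileSpec) -> TemperatureProfile:
    """Draw one reproducible profile from the spec.

    Excursion windows are placed without overlap (rejection sampling on a
    seeded RNG), each lifting the affected readings by the excursion
    magnitude; stage means and durations are honoured exactly.
    """
    rng = np.random.default_rng(spec.seed)
    dt_d = spec.sampling_interval_s / SECONDS_PER_DAY
    temps: list[float] = []
    for mean_c, dur_d in spec.stages:
        n = max(1, int(round(dur_d / dt_d)))
        temps.extend(mean_c + spec.noise_sd_c * rng.standard_normal(n))
    temps_arr = np.asarray(temps)

    n_total = temps_arr.size
    exc_len = max(1, int(round(spec.excursion_duration_min * 60.0 / spec.sampling_interval_s)))
    taken = np.zeros(n_total, dtype=bool)
    placed = 0
    attempts = 0
    while placed < spec.n_excursions and attempts < 1000 * max(1, spec.n_excursions):
        attempts += 1
        start = int(rng.integers(0, max(1, n_total - exc_len)))
        window = slice(start, start + exc_len)
        # keep one clean reading on each side so events stay disjoint
        guard = slice(max(0, start - 1), min(n_total, start + exc_len + 1))
        if taken[guard].any():
            continue
        temps_arr[window] += spec.excursion_magnitude_c
        taken[guard] = True
        placed += 1
    if placed < spec.n_excursions:
        raise ValueError(
            f"could only place {placed}/{spec.n_excursions} disjoint excursions "
            f"in {n_total} readings")
    return TemperatureProfile.from_readings(
        temps_arr, interval_s=spec.sampling_interval_s, stage="synthetic")
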