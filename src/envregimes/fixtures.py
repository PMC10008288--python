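"""Synthetic daily-discharge-style fixtures.

The generator emulates the qualitative shape of a year of daily stream
discharge plus a 13-date sampling schedule whose first date marks study
initialization.  Values are built on the log scale as an AR(1) process
around ``log(baseline)`` with Gaussian innovations, plus Poisson-timed
multiplicative pulses that decay over about three days — so the series is
strictly positive, autocorrelated, and right-skewed with occasional high
spikes, the way stream discharge looks.  It makes no hydrological realism
claim beyond that shape.

All randomness flows from one explicit integer seed; there is no global
generator state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .series_io import EnvSeries, SamplingSchedule

__all__ = ["FixtureSpec", "simulate_series", "simulate_schedule"]

#: e-folding time (days) of a pulse's decay back to baseline.
_PULSE_DECAY_DAYS = 3.0


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic series and schedule.

    Attributes
    ----------
    seed
        Seed for all randomness.
    n_days
        Series length; one value per day.
    baseline
        Geometric-mean level of the series (units arbitrary, e.g. m3/s).
    ar_coef
        Log-scale AR(1) coefficient in [0, 1); 0.7 gives day-to-day
        persistence typical of small streams.
    pulse_rate
        Expected number of high pulses per 30 days.
    pulse_scale
        Peak multiplicative magnitude of a pulse (5 = a fivefold spike).
    n_schedule_dates
        Schedule length including the initialization anchor.
    noise_sd
        Standard deviation of the log-scale innovations.
    jitter_days
        Max +/- shift applied to interior schedule dates.
    start_date
        Calendar date of the first series value.
    """

    seed: int
    n_days: int = 365
    baseline: float = 10.0
    ar_coef: float = 0.7
    pulse_rate: float = 2.0
    pulse_scale: float = 5.0
    n_schedule_dates: int = 13
    noise_sd: float = 0.15
    jitter_days: int = 3
    start_date: str = "2019-01-01"

    def __post_init__(self) -> None:
        if self.n_days < self.n_schedule_dates:
            raise ValidationError("n_days must be >= n_schedule_dates")
        if self.n_schedule_dates < 2:
            raise ValidationError("n_schedule_dates must be >= 2")
        if self.baseline <= 0:
            raise ValidationError("baseline must be positive")
        if not (0 <= self.ar_coef < 1):
            raise ValidationError("ar_coef must lie in [0, 1)")
        if self.pulse_rate < 0 or self.noise_sd < 0 or self.pulse_scale < 1:
            raise ValidationError("pulse_rate, noise_sd >= 0 and pulse_scale >= 1 required")


def simulate_series(spec: FixtureSpec, name: str = "Discharge") -> EnvSeries:
    """Generate a strictly positive daily series per the fixture spec.

    Log-scale AR(1) around ``log(baseline)`` with innovations of sd
    ``noise_sd``, plus pulses arriving as a Bernoulli process at rate
    ``pulse_rate`` per 30 days; each pulse adds ``log(pulse_scale)`` to the
    log level, decaying exponentially over ~3 days.  Reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_days
    mu = np.log(spec.baseline)

    log_level = np.empty(n)
    level = 0.0
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    for t in range(n):
        level = spec.ar_coef * level + noise[t]
        log_level[t] = mu + level

    p_day = min(spec.pulse_rate / 30.0, 1.0)
    pulse_log = np.zeros(n)
    if p_day > 0 and spec.pulse_scale > 1:
        onsets = np.flatnonzero(rng.random(n) < p_day)
        amp = np.log(spec.pulse_scale)
        for t0 in onsets:
            tail = np.arange(n - t0)
            pulse_log[t0:] += amp * np.exp(-tail / _PULSE_DECAY_DAYS)

    values = np.exp(log_level + pulse_log)
    timestamps = pd.date_range(spec.start_date, periods=n, freq="D")
    return EnvSeries(name=name, timestamps=timestamps, values=values)


def simulate_schedule(spec: FixtureSpec, series: EnvSeries) -> SamplingSchedule:
    """Generate an anchored sampling schedule spanning the series.

    The first date is the series start (the initialization anchor); the
    remaining dates are evenly spaced across the record with a seeded
    jitter of up to ``jitter_days``, kept strictly increasing and never
    past the series end.
    """
    if len(series) < spec.n_schedule_dates:
        raise ValidationError("series shorter than the requested schedule")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = spec.n_schedule_dates
    last = len(series) - 1
    ideal = np.round(np.linspace(0, last, n)).astype(int)
    offsets = ideal.copy()
    if spec.jitter_days > 0:
        jit = rng.integers(-spec.jitter_days, spec.jitter_days + 1, size=n - 1)
        offsets[1:] = np.clip(ideal[1:] + jit, 1, last)
        # enforce strict increase left to right
        for i in range(1, n):
            offsets[i] = max(offsets[i], offsets[i - 1] + 1)
        if offsets[-1] > last:
            raise ValidationError("schedule spacing infeasible for this jitter")
    dates = series.timestamps[offsets]
    return SamplingSchedule(dates=pd.DatetimeIndex(dates), has_init_anchor=True)
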