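import numpy as np
import pandas as pd
import pytest

from envregimes import EnvSeries, FixtureSpec, SamplingSchedule, simulate_schedule, simulate_series


@pytest.fixture
def daily_series():
    """30 deterministic daily values, 2019-01-01..2019-01-30."""
    ts = pd.date_range("2019-01-01", periods=30, freq="D")
    values = 10 + np.sin(np.arange(30) / 3.0) * 4
    return EnvSeries(name="Discharge", timestamps=ts, values=values)


@pytest.fixture
def anchored_schedule():
    """Anchor at day 1 plus three sampling dates (days 10, 20, 30)."""
    return SamplingSchedule(
        dates=pd.DatetimeIndex(["2019-01-01", "2019-01-10", "2019-01-20", "2019-01-30"]),
        has_init_anchor=True,
    )


@pytest.fixture
def fixture_pair():
    """Default synthetic year plus its 13-date anchored schedule."""
    spec = FixtureSpec(seed=42)
    series = simulate_series(spec)
    return series, simulate_schedule(spec, series)


def random_window(rng, n_max=30, missing_prob=0.0):
    """A random window of positive values, optionally with NaN holes."""
    n = int(rng.integers(2, n_max + 1))
    vals = rng.lognormal(mean=1.0, sigma=0.8, size=n)
    if missing_prob > 0:
        holes = rng.random(n) < missing_prob
        if holes.all():
            holes[int(rng.integers(n))] = False
        vals[holes] = np.nan
    return vals
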