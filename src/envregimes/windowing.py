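"""Realizing windows from a sampling schedule.

Two window rules exist.  ``betw_samt`` (the default) spans the days between
two successive schedule dates: window *i* covers ``(previous date, sample
date i]`` — half-open on the left so consecutive windows tile the record
with no overlap and no gap, inclusive of the sampling date itself on the
right.  ``fixed_lookback`` of length *L* covers the *L* steps ending at the
sampling date (``days_bf`` in the field's usage), truncated at the series
start with a warning.

The first between-samples window starts the step after the initialization
anchor when the schedule has one; otherwise the ``first_window`` policy
decides (start at the series origin with a warning, or drop the first
sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError, WindowError
from .series_io import EnvSeries, SamplingSchedule

logger = logging.getLogger("envregimes")

__all__ = ["WindowSpec", "Window", "build_windows", "slice_window", "parse_window_token"]


@dataclass(frozen=True)
class WindowSpec:
    """A window rule: between-samples, or a fixed look-back of ``length`` steps."""

    kind: Literal["betw_samt", "fixed_lookback"]
    length: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "fixed_lookback":
            if self.length is None or self.length < 1:
                raise ValidationError(f"fixed_lookback needs length >= 1, got {self.length}")
        elif self.kind == "betw_samt":
            if self.length is not None:
                raise ValidationError("betw_samt takes no length")
        else:
            raise ValidationError(f"unknown window kind {self.kind!r}")
        if not self.label:
            default = "BetwSamT" if self.kind == "betw_samt" else f"{self.length}d"
            object.__setattr__(self, "label", default)


def parse_window_token(token: str | int) -> WindowSpec:
    """Parse a config token: ``BetwSamT`` or an integer step count like ``7``."""
    if isinstance(token, int):
        return WindowSpec(kind="fixed_lookback", length=token)
    text = str(token).strip()
    if text.lower() == "betwsamt":
        return WindowSpec(kind="betw_samt")
    try:
        length = int(text.removesuffix("d"))
    except ValueError:
        raise ValidationError(f"cannot parse window token {token!r}") from None
    return WindowSpec(kind="fixed_lookback", length=length)


@dataclass(frozen=True)
class Window:
    """A realized date interval ending at a sampling date, with its values.

    ``values`` holds one entry per grid timestamp in ``[start, end]``; NaN
    marks missing measurements.  ``n`` counts the non-missing values.
    """

    sample_date: pd.Timestamp
    start: pd.Timestamp
    end: pd.Timestamp
    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"window for {self.sample_date.date()}: start {self.start.date()} "
                f"after end {self.end.date()}"
            )


def _extract(series: EnvSeries, start: pd.Timestamp, end: pd.Timestamp) -> np.ndarray:
    mask = (series.timestamps >= start) & (series.timestamps <= end)
    return series.values[mask]


def build_windows(
    schedule: SamplingSchedule,
    spec: WindowSpec,
    series: EnvSeries,
    first_window: Literal["anchor", "origin", "drop"] = "origin",
    on_empty: Literal["raise", "keep"] = "raise",
) -> list[Window]:
    """Realize one window per sampling event, in date order.

    Parameters
    ----------
    first_window
        Only consulted for ``betw_samt`` when the schedule has no
        initialization anchor: ``origin`` starts the first window at the
        series' first timestamp (warned), ``drop`` skips the first sample.
    on_empty
        ``raise`` (default) raises :class:`WindowError` when a window holds
        zero non-missing values; ``keep`` returns it (the engine then emits
        missing cells with a warning).
    """
    schedule.check_within(series)
    windows: list[Window] = []
    step = series.step

    if spec.kind == "betw_samt":
        dates = list(schedule.dates)
        if schedule.has_init_anchor or first_window == "anchor":
            pairs = list(zip(dates[:-1], dates[1:]))
        elif first_window == "origin":
            logger.warning(
                "no initialization anchor: first window starts at series origin %s",
                series.start.date(),
            )
            # series.start - step so the half-open left bound lands on the origin
            pairs = [(series.start - step, dates[0])] + list(zip(dates[:-1], dates[1:]))
        elif first_window == "drop":
            pairs = list(zip(dates[:-1], dates[1:]))
        else:
            raise ValidationError(f"unknown first_window policy {first_window!r}")
        for prev, cur in pairs:
            start = prev + step
            windows.append(_realize(series, start, cur, on_empty))
    else:
        assert spec.length is not None
        for cur in schedule.sampling_dates:
            start = cur - (spec.length - 1) * step
            if start < series.start:
                logger.warning(
                    "look-back window for %s truncated at series start %s",
                    cur.date(),
                    series.start.date(),
                )
                start = series.start
            windows.append(_realize(series, start, cur, on_empty))
    return windows


def _realize(series, start, end, on_empty) -> Window:
    vals = _extract(series, start, end)
    n = int(np.sum(~np.isnan(vals)))
    if n == 0 and on_empty == "raise":
        raise WindowError(f"window ending {end.date()} contains no non-missing values")
    return Window(sample_date=end, start=start, end=end, values=vals, n=n)


def slice_window(series: EnvSeries, window: Window) -> np.ndarray:
    """Non-missing series values inside the window, original order kept."""
    vals = _extract(series, window.start, window.end)
    return vals[~np.isnan(vals)]
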