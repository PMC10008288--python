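"""Reading, validating and writing environmental time series and schedules.

The on-disk contract is deliberately plain: CSV with a header row and
ISO-8601 dates.  A series file is either *wide* (one date column followed by
one column per variable) or *long* (``date,variable,value``).  A sampling
schedule is a one-column CSV or a newline-delimited list of dates, the first
of which may mark study initialization rather than an actual sample.

Missing values are accepted as empty fields or ``NA`` on input and written
as empty fields on output, so result tables round-trip byte-stably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import FormatError, GapError, ValidationError

logger = logging.getLogger("envregimes")

__all__ = [
    "EnvSeries",
    "SamplingSchedule",
    "RegimeTable",
    "load_series",
    "load_schedule",
    "validate_regular",
    "write_table",
    "read_table",
]

#: Missing-value spellings accepted on input.
_NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass(frozen=True)
class EnvSeries:
    """One environmental variable measured at a regular cadence.

    Parameters
    ----------
    name
        Variable name (e.g. ``"Discharge"``); used as a column prefix when
        several variables share one result table.
    timestamps
        Strictly increasing measurement dates.
    values
        Measurements, one per timestamp; NaN marks a missing measurement.
        Units depend on the variable.
    step
        Declared cadence between consecutive measurements (1 day by
        default; sub-daily steps are accepted).
    """

    name: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    step: pd.Timedelta = pd.Timedelta(days=1)

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if len(ts) < 2:
            raise ValidationError(
                f"series {self.name!r}: need at least 2 observations, got {len(ts)}"
            )
        if len(ts) != len(vals):
            raise ValidationError(
                f"series {self.name!r}: {len(ts)} timestamps but {len(vals)} values"
            )
        if not ts.is_monotonic_increasing or ts.has_duplicates:
            dup = ts[ts.duplicated()]
            if len(dup):
                raise ValidationError(
                    f"series {self.name!r}: duplicate timestamp {dup[0].date()}"
                )
            raise ValidationError(f"series {self.name!r}: timestamps not increasing")
        if self.step <= pd.Timedelta(0):
            raise ValidationError(f"series {self.name!r}: step must be positive")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def start(self) -> pd.Timestamp:
        return self.timestamps[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.timestamps[-1]

    def to_pandas(self) -> pd.Series:
        """Return the series as a pandas Series indexed by timestamp."""
        return pd.Series(self.values, index=self.timestamps, name=self.name)

    @property
    def is_regular(self) -> bool:
        """True when consecutive timestamps are exactly ``step`` apart."""
        diffs = np.diff(self.timestamps.asi8)
        return bool(np.all(diffs == self.step.value))


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered biological sampling dates, optionally led by an init anchor.

    When ``has_init_anchor`` is true the first date marks study
    initialization: it bounds the first between-samples window on the left
    but never produces an output row.
    """

    dates: pd.DatetimeIndex
    has_init_anchor: bool = False

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        if not dates.is_monotonic_increasing or dates.has_duplicates:
            raise ValidationError("schedule dates must be strictly increasing")
        min_len = 2 if self.has_init_anchor else 1
        if len(dates) < min_len:
            raise ValidationError(
                f"schedule needs at least {min_len} dates "
                f"(has_init_anchor={self.has_init_anchor}), got {len(dates)}"
            )
        object.__setattr__(self, "dates", dates)

    @property
    def sampling_dates(self) -> pd.DatetimeIndex:
        """Dates that produce output rows (anchor excluded)."""
        return self.dates[1:] if self.has_init_anchor else self.dates

    @property
    def n_events(self) -> int:
        return len(self.sampling_dates)

    def check_within(self, series: EnvSeries) -> None:
        """Raise unless every schedule date lies inside the series span."""
        if self.dates[0] < series.start or self.dates[-1] > series.end:
            raise ValidationError(
                f"schedule dates [{self.dates[0].date()}, {self.dates[-1].date()}] "
                f"fall outside series {series.name!r} span "
                f"[{series.start.date()}, {series.end.date()}]"
            )


@dataclass
class RegimeTable:
    """One row per sampling event, one column per variable x window x index.

    ``data`` is indexed by sampling date (index name ``SampleDate``); column
    names follow ``<variable>_<window>.<code>`` with the variable prefix
    omitted when the table holds a single variable.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data.index.name = "SampleDate"

    @property
    def sample_dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def _parse_dates(raw: pd.Series, path: Path) -> pd.DatetimeIndex:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.argmax(parsed.isna().to_numpy()))
        raise FormatError(
            f"{path}: unparseable date {raw.iloc[row]!r} at data row {row + 1}"
        )
    return pd.DatetimeIndex(parsed)


def _infer_step(ts: pd.DatetimeIndex) -> pd.Timedelta:
    diffs = pd.Series(ts).diff().dropna()
    if diffs.empty:
        return pd.Timedelta(days=1)
    return pd.Timedelta(diffs.mode().iloc[0])


def load_series(
    path: str | Path,
    layout: Literal["wide", "long"] = "wide",
    step: pd.Timedelta | str | None = None,
) -> list[EnvSeries]:
    """Read one or more environmental series from a CSV file.

    Parameters
    ----------
    path
        CSV with a header row; first column holds ISO-8601 dates.
    layout
        ``"wide"``: every column after the date column is one variable.
        ``"long"``: columns are date, variable name, value.
    step
        Declared cadence; inferred from the most common spacing when None.

    Returns
    -------
    list of EnvSeries, one per variable, rows sorted by date.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a date column plus at least one value column")
    dates = _parse_dates(df.iloc[:, 0], path)

    if layout == "long":
        if df.shape[1] != 3:
            raise FormatError(f"{path}: long layout needs exactly 3 columns")
        frame = pd.DataFrame(
            {
                "variable": df.iloc[:, 1].to_numpy(),
                "value": pd.to_numeric(df.iloc[:, 2], errors="raise").to_numpy(),
            },
            index=dates,
        )
        out = []
        for var in sorted(frame["variable"].unique()):
            sub = frame[frame["variable"] == var].sort_index()
            out.append(_make_series(str(var), sub.index, sub["value"].to_numpy(), step, path))
        return out

    if layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    order = np.argsort(dates.asi8, kind="stable")
    dates = dates[order]
    out = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="raise").to_numpy()[order]
        out.append(_make_series(str(col), dates, vals, step, path))
    return out


def _make_series(name, ts, values, step, path) -> EnvSeries:
    ts = pd.DatetimeIndex(ts)
    if ts.has_duplicates:
        dup = ts[ts.duplicated()][0]
        raise ValidationError(f"{path}: duplicate timestamp {dup.date()} for variable {name!r}")
    resolved = pd.Timedelta(step) if step is not None else _infer_step(ts)
    return EnvSeries(name=name, timestamps=ts, values=values, step=resolved)


def load_schedule(path: str | Path, has_init_anchor: bool = False) -> SamplingSchedule:
    """Read a sampling schedule: one ISO-8601 date per line (header optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip() and ln.strip() != ","
    ]
    if not lines:
        raise FormatError(f"{path}: no dates found")
    # Tolerate a header line (e.g. "date") on the first row only.
    first = pd.to_datetime(lines[0], format="ISO8601", errors="coerce")
    if pd.isna(first):
        lines = lines[1:]
        if not lines:
            raise FormatError(f"{path}: no dates found after header")
    parsed = pd.to_datetime(pd.Series(lines), format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.argmax(parsed.isna().to_numpy()))
        raise FormatError(f"{path}: unparseable date {lines[row]!r}")
    return SamplingSchedule(dates=pd.DatetimeIndex(parsed), has_init_anchor=has_init_anchor)


def validate_regular(
    series: EnvSeries, policy: Literal["strict", "fill_missing"] = "strict"
) -> EnvSeries:
    """Enforce a gapless regular grid at the series' declared step.

    ``strict`` raises :class:`GapError` on the first gap; ``fill_missing``
    inserts NaN rows for every absent timestamp and logs how many.
    """
    full = pd.date_range(series.start, series.end, freq=series.step)
    if len(full) == len(series) and series.is_regular:
        return series
    missing = full.difference(series.timestamps)
    if len(missing) == 0:
        # timestamps not on the step grid at all
        raise GapError(
            f"series {series.name!r}: timestamps are not aligned to step {series.step}"
        )
    if policy == "strict":
        raise GapError(
            f"series {series.name!r}: {len(missing)} missing timestamps, "
            f"first at {missing[0].date()}"
        )
    if policy != "fill_missing":
        raise ValueError(f"unknown policy {policy!r}")
    filled = series.to_pandas().reindex(full)
    logger.warning(
        "series %r: filled %d missing timestamps with NA", series.name, len(missing)
    )
    return EnvSeries(
        name=series.name, timestamps=full, values=filled.to_numpy(), step=series.step
    )


def write_table(table: RegimeTable, path: str | Path) -> None:
    """Write a RegimeTable as CSV: ``SampleDate`` first, then index columns.

    Column order is fixed by construction (variables alphabetical, windows
    in configuration order, index codes in their standard order) so outputs
    are byte-comparable across runs.  Missing cells become empty fields.
    """
    if len(table.columns) == 0:
        raise ValidationError("refusing to write a table with no index columns")
    out = table.data.copy()
    out.index = pd.DatetimeIndex(out.index).strftime("%Y-%m-%d")
    out.index.name = "SampleDate"
    out.to_csv(Path(path), na_rep="")


def read_table(path: str | Path) -> RegimeTable:
    """Read back a CSV written by :func:`write_table`."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if df.columns[0] != "SampleDate":
        raise FormatError(f"{path}: first column must be 'SampleDate'")
    idx = _parse_dates(df["SampleDate"], Path(path))
    data = df.drop(columns="SampleDate").apply(pd.to_numeric)
    data.index = idx
    return RegimeTable(data=data)
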