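"""Dated daily time series: the currency passed between all pipeline stages.

A :class:`TimeSeries` is a strictly daily-sampled real-valued sequence with
calendar dates.  Validation is strict on purpose: the decomposition assumes a
regular sampling grid, so gaps and duplicates are errors, never silently
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeries", "read_timeseries", "write_timeseries"]


@dataclass(frozen=True)
class TimeSeries:
    """A regularly sampled daily series.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly increasing calendar dates with a constant 1-day step.
    values : numpy.ndarray
        Real values, same length as ``dates``.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        dates = pd.DatetimeIndex(self.dates)
        object.__setattr__(self, "dates", dates)
        if len(dates) != len(values):
            raise ValueError(
                f"dates ({len(dates)}) and values ({len(values)}) differ in length"
            )
        if len(dates) < 8:
            raise ValueError(f"series too short: n={len(dates)} < 8")
        step = np.diff(dates.values).astype("timedelta64[D]")
        bad = np.nonzero(step != np.timedelta64(1, "D"))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"dates must advance by exactly one day; violation after "
                f"{dates[i].date()} (row {i + 1}: {dates[i + 1].date()})"
            )
        if not np.all(np.isfinite(values)):
            i = int(np.nonzero(~np.isfinite(values))[0][0])
            raise ValueError(f"non-finite value at {dates[i].date()} (row {i + 1})")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @classmethod
    def from_start(cls, start: str, values: np.ndarray) -> "TimeSeries":
        """Build a series from a start date and values (one per day)."""
        values = np.asarray(values, dtype=float)
        dates = pd.date_range(start, periods=len(values), freq="D")
        return cls(dates, values)

    def window_slice(self, start, end) -> slice:
        """Positional slice for the inclusive date window [start, end]."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        if start > end:
            raise ValueError(f"window start {start.date()} after end {end.date()}")
        if start < self.dates[0] or end > self.dates[-1]:
            raise ValueError(
                f"window {start.date()}..{end.date()} outside series range "
                f"{self.dates[0].date()}..{self.dates[-1].date()}"
            )
        i0 = int(self.dates.searchsorted(start))
        i1 = int(self.dates.searchsorted(end))
        return slice(i0, i1 + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "value": self.values})


def read_timeseries(path) -> TimeSeries:
    """Read a ``date,value`` CSV into a validated :class:`TimeSeries`.

    Raises a descriptive error naming the offending row on the first gap,
    duplicate date, or non-numeric value.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"date", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected header with columns {sorted(required)}")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable date: {exc}") from None
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        i = int(values.isna().idxmax())
        raise ValueError(
            f"{path}: non-numeric value {df['value'].iloc[i]!r} at row {i + 2} "
            f"(date {df['date'].iloc[i]})"
        )
    return TimeSeries(pd.DatetimeIndex(dates), values.to_numpy(dtype=float))


def write_timeseries(series: TimeSeries, path) -> None:
    """Write a series as ``date,value`` CSV with round-trip float precision."""
    df = series.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.17g")
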