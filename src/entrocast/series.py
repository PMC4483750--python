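"""Daily concentration series: data model, CSV I/O, splitting, monthly aggregation.

The universal input of the package is a univariate daily series of strictly
positive concentrations (µg/m³).  Positivity is enforced at ingest because the
downstream relative-error indexes (MPE, the Theil coefficient) divide by the
observed values.  Dates must be consecutive calendar days by default; the
forecasters consume values by position, so an explicit ``allow_gaps`` mode
re-indexes by observation order instead of rejecting gapped records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "MonthlySummary",
    "read_series",
    "write_series",
    "monthly_means",
    "split_holdout",
]


@dataclass(frozen=True)
class DailySeries:
    """A dated sequence of strictly positive daily concentrations.

    Parameters
    ----------
    dates
        Strictly increasing calendar dates, one per observation.  Unless
        ``allow_gaps`` is set, the dates must be consecutive days.
    values
        Concentrations in µg/m³; every value must be finite and > 0.
    allow_gaps
        Permit missing calendar days.  The forecasters treat observations
        positionally, so a gapped series is modelled as if contiguous.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(dates) != len(values):
            raise ValueError(
                f"dates ({len(dates)}) and values ({len(values)}) differ in length"
            )
        if len(values) == 0:
            raise ValueError("series must contain at least one observation")
        if not np.all(np.isfinite(values)):
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise ValueError(f"non-finite value at row {bad}")
        if np.any(values <= 0):
            bad = int(np.flatnonzero(values <= 0)[0])
            raise ValueError(
                f"non-positive value {values[bad]} at row {bad}: concentrations "
                "must be > 0 (relative-error metrics divide by them)"
            )
        if len(dates) > 1:
            deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
            if np.any(deltas <= 0):
                bad = int(np.flatnonzero(deltas <= 0)[0])
                raise ValueError(
                    f"dates not strictly increasing at row {bad + 1} ({dates[bad + 1].date()})"
                )
            if not self.allow_gaps and np.any(deltas != 1):
                bad = int(np.flatnonzero(deltas != 1)[0])
                raise ValueError(
                    f"calendar gap after {dates[bad].date()}: dates must be "
                    "consecutive days (pass allow_gaps=True to index by position)"
                )

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self, date_column: str = "date", value_column: str = "value") -> pd.DataFrame:
        return pd.DataFrame({date_column: self.dates, value_column: self.values})

    def slice(self, start: int, stop: int) -> "DailySeries":
        """Positional sub-series (used by the train/holdout split)."""
        return DailySeries(self.dates[start:stop], self.values[start:stop], self.allow_gaps)

    @classmethod
    def from_values(
        cls,
        values: Sequence[float] | np.ndarray,
        start: str | pd.Timestamp = "2013-12-02",
        allow_gaps: bool = False,
    ) -> "DailySeries":
        """Build a series from bare values with consecutive dates from ``start``."""
        values = np.asarray(values, dtype=float)
        dates = pd.date_range(start, periods=len(values), freq="D")
        return cls(dates, values, allow_gaps)


@dataclass(frozen=True)
class MonthlySummary:
    """Arithmetic mean of one calendar month's daily values."""

    year: int
    month: int
    mean_value: float
    n_days: int


def read_series(
    path,
    date_column: str = "date",
    value_column: str = "value",
    allow_gaps: bool = False,
) -> DailySeries:
    """Read a daily series from CSV.

    Accepts ISO-8601 dates as well as the slash form ``2015/1/22``.  Rows are
    sorted by date.  Non-numeric, non-positive or duplicate entries are
    rejected with the offending row named.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (date_column, value_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (have {list(df.columns)})")
    try:
        dates = pd.to_datetime(df[date_column], format="mixed")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in column {date_column!r}: {exc}") from exc
    values = pd.to_numeric(df[value_column], errors="coerce")
    if values.isna().any():
        bad = int(values.isna().idxmax())
        raise ValueError(f"non-numeric value {df[value_column].iloc[bad]!r} at row {bad}")
    if dates.duplicated().any():
        bad = int(dates.duplicated().idxmax())
        raise ValueError(f"duplicate date {dates.iloc[bad].date()} at row {bad}")
    order = np.argsort(dates.values, kind="stable")
    return DailySeries(
        pd.DatetimeIndex(dates.values[order]),
        values.to_numpy()[order],
        allow_gaps=allow_gaps,
    )


def write_series(
    series: DailySeries,
    path,
    date_column: str = "date",
    value_column: str = "value",
) -> None:
    """Write a series to CSV with ISO dates and full ``repr`` precision."""
    df = series.to_frame(date_column, value_column)
    df[date_column] = df[date_column].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.17g")


def monthly_means(series: DailySeries) -> list[MonthlySummary]:
    """Per-calendar-month arithmetic means, in chronological order."""
    frame = pd.DataFrame({"value": series.values}, index=series.dates)
    grouped = frame.groupby([frame.index.year, frame.index.month])["value"]
    return [
        MonthlySummary(year=int(y), month=int(m), mean_value=float(g.mean()), n_days=int(g.size))
        for (y, m), g in grouped
    ]


def split_holdout(series: DailySeries, n_holdout: int) -> tuple[DailySeries, DailySeries]:
    """Split into the leading training block and the final ``n_holdout`` points."""
    if not 0 < n_holdout < len(series):
        raise ValueError(
            f"n_holdout must satisfy 0 < n_holdout < {len(series)}, got {n_holdout}"
        )
    cut = len(series) - n_holdout
    return series.slice(0, cut), series.slice(cut, len(series))
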