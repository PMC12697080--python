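"""Calendar-day percentile climatologies and yearly heatwave indices.

Conventions (recorded, configurable where noted):

* percentile estimator: linear interpolation between order statistics
  (numpy's default, the classical "type 7" rule);
* exceedance is strict (``value > threshold``);
* heatwave = maximal run of >= ``min_duration`` consecutive Tmax
  exceedance days; runs crossing Dec-31 are not split and are attributed
  to the year containing the start date;
* yearly magnitude HWM = mean Tmax over all heatwave days of the year
  (0.0 when no event); amplitude HWA = hottest event day (NaN when no
  event).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .series import DailySeries

__all__ = [
    "ThresholdClimatology",
    "HeatwaveEvent",
    "YearlyHeatwaveIndices",
    "calendar_day_index",
    "calendar_day_percentile",
    "warm_day_fraction",
    "detect_heatwaves",
    "yearly_indices",
    "indices_table",
    "write_indices_csv",
    "read_indices_csv",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ("tx90p", "tn90p", "hwn", "hwf", "hwd", "hwm", "hwa")

DEFAULT_MIN_DURATION = 3       # ETCCDI/ClimPACT heatwave-aspects convention
DEFAULT_WINDOW_HALFWIDTH = 7   # 15-day centered window


def calendar_day_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to a 1..366 calendar-day index (Feb-29 = 60, Mar-1 = 61).

    Non-leap years skip index 60 so that identical month/day pairs share
    an index across leap and non-leap years.
    """
    doy = dates.dayofyear.to_numpy().copy()
    nonleap = ~dates.is_leap_year
    doy[nonleap & (doy >= 60)] += 1
    return doy


@dataclass
class ThresholdClimatology:
    """Per-calendar-day percentile thresholds from a base period."""

    variable: str
    base_start: int
    base_end: int
    window_halfwidth: int
    q: float
    thresholds: np.ndarray  # shape (366,), index 0 = Jan-1

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (366,):
            raise DataError("thresholds must have exactly 366 entries")
        if not np.all(np.isfinite(self.thresholds)):
            raise DataError("thresholds must all be finite")

    def for_dates(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return self.thresholds[calendar_day_index(dates) - 1]


def calendar_day_percentile(
    series: DailySeries,
    variable: str = "tmax",
    base_period: tuple[int, int] | None = None,
    q: float = 90.0,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
) -> ThresholdClimatology:
    """q-th percentile of all base-period values within +-window of each
    calendar day, window wrapping across the year boundary."""
    if not (0 < q < 100):
        raise ValueError("q must be in (0, 100)")
    years = series.years
    if base_period is None:
        base_period = (int(years.min()), int(years.max()))
    b0, b1 = base_period
    if b0 < years.min() or b1 > years.max():
        raise DataError(
            f"base period {b0}-{b1} not covered by series span "
            f"{years.min()}-{years.max()}"
        )
    base = series.period_slice(b0, b1)
    values = base.values(variable)
    cal = calendar_day_index(base.dates)

    # bucket values by calendar day once, then pool windows per target day
    buckets: list[np.ndarray] = [values[cal == d] for d in range(1, 367)]
    h = window_halfwidth
    thresholds = np.empty(366)
    for d in range(366):
        members = [(d + k) % 366 for k in range(-h, h + 1)]
        pool = np.concatenate([buckets[m] for m in members]) if members else np.empty(0)
        if pool.size == 0:
            raise DataError(f"empty window for calendar day {d + 1}")
        thresholds[d] = np.percentile(pool, q)
    return ThresholdClimatology(variable, b0, b1, window_halfwidth, q, thresholds)


def warm_day_fraction(
    series: DailySeries, clim: ThresholdClimatology, year: int
) -> float:
    """Percentage of the year's days strictly exceeding the calendar-day
    threshold (TX90p for tmax climatologies, TN90p for tmin)."""
    sub = series.year_slice(year)
    values = sub.values(clim.variable)
    thr = clim.for_dates(sub.dates)
    return 100.0 * float(np.mean(values > thr))


@dataclass(frozen=True)
class HeatwaveEvent:
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration: int
    peak: float
    mean_intensity: float


def _exceedance_runs(exceed: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    padded = np.concatenate(([False], exceed, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_heatwaves(
    series: DailySeries,
    clim: ThresholdClimatology,
    year: int,
    min_duration: int = DEFAULT_MIN_DURATION,
) -> list[HeatwaveEvent]:
    """Maximal runs of consecutive Tmax-threshold-exceedance days with
    length >= min_duration that *start* in ``year``.

    Runs are found over the whole series so an event crossing Dec-31
    keeps its full duration and is counted in its start year.
    """
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    tmax = series.tmax
    thr = clim.for_dates(series.dates)
    exceed = tmax > thr
    events = []
    for s, e in _exceedance_runs(exceed):
        if e - s + 1 < min_duration:
            continue
        start_date = series.dates[s]
        if start_date.year != year:
            continue
        seg = tmax[s : e + 1]
        events.append(
            HeatwaveEvent(
                start_date=start_date,
                end_date=series.dates[e],
                duration=e - s + 1,
                peak=float(seg.max()),
                mean_intensity=float(seg.mean()),
            )
        )
    return events


@dataclass(frozen=True)
class YearlyHeatwaveIndices:
    station_id: str
    year: int
    tx90p: float
    tn90p: float
    hwn: int
    hwf: int
    hwd: int
    hwm: float
    hwa: float  # NaN when no event


def yearly_indices(
    series: DailySeries,
    clim_tx: ThresholdClimatology,
    clim_tn: ThresholdClimatology,
    year: int,
    min_duration: int = DEFAULT_MIN_DURATION,
) -> YearlyHeatwaveIndices:
    events = detect_heatwaves(series, clim_tx, year, min_duration)
    hwn = len(events)
    hwf = sum(ev.duration for ev in events)
    hwd = max((ev.duration for ev in events), default=0)
    if events:
        # weighted by duration: mean over all heatwave days of the year
        total = sum(ev.mean_intensity * ev.duration for ev in events)
        hwm = total / hwf
        hwa = max(ev.peak for ev in events)
    else:
        hwm = 0.0
        hwa = float("nan")
    return YearlyHeatwaveIndices(
        station_id=series.station_id,
        year=year,
        tx90p=warm_day_fraction(series, clim_tx, year),
        tn90p=warm_day_fraction(series, clim_tn, year),
        hwn=hwn,
        hwf=hwf,
        hwd=hwd,
        hwm=hwm,
        hwa=hwa,
    )


def indices_table(
    series: DailySeries,
    clim_tx: ThresholdClimatology,
    clim_tn: ThresholdClimatology,
    years: Sequence[int] | None = None,
    min_duration: int = DEFAULT_MIN_DURATION,
) -> pd.DataFrame:
    """Tidy frame of yearly indices, one row per station-year."""
    if years is None:
        years = series.years.tolist()
    rows = [
        yearly_indices(series, clim_tx, clim_tn, int(y), min_duration).__dict__
        for y in years
    ]
    return pd.DataFrame(rows)


def write_indices_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Missing hwa (no-event years) is written as an empty field."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6f", na_rep="")
    return path


def read_indices_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
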