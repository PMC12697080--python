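"""Daily temperature series container and station catalogue I/O.

A :class:`DailySeries` is the atom of every downstream computation: one
station's gap-free, strictly increasing daily record of maximum and minimum
near-surface temperature in degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "DailySeries",
    "StationSpec",
    "read_series_csv",
    "write_series_csv",
    "read_catalogue_csv",
    "write_catalogue_csv",
    "series_to_dataset",
    "write_series_netcdf",
    "read_series_netcdf",
]


@dataclass(frozen=True)
class StationSpec:
    """Location metadata for one station."""

    station_id: str
    lon: float
    lat: float
    country: str


@dataclass
class DailySeries:
    """One station's dated daily Tmax/Tmin record.

    Parameters
    ----------
    station_id
        Unique station label.
    dates
        Strictly increasing, gap-free daily ``DatetimeIndex``.
    tmax, tmin
        Daily maximum / minimum temperature in degC, ``tmax >= tmin``
        elementwise.
    attrs
        Free-form metadata (e.g. ground-truth parameters from the
        synthetic generator).
    """

    station_id: str
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        n = len(self.dates)
        if len(self.tmax) != n or len(self.tmin) != n:
            raise DataError("dates, tmax and tmin must have equal length")
        if n == 0:
            raise DataError("empty series")
        deltas = np.diff(self.dates.values.astype("datetime64[D]").astype(int))
        if np.any(deltas != 1):
            raise DataError("dates must be strictly increasing and gap-free")
        if np.any(self.tmax < self.tmin):
            raise DataError("tmax < tmin encountered")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.dates.year)

    def values(self, variable: str) -> np.ndarray:
        if variable not in ("tmax", "tmin"):
            raise ValueError(f"unknown variable {variable!r}")
        return getattr(self, variable)

    def year_slice(self, year: int) -> "DailySeries":
        mask = self.dates.year == year
        if not mask.any():
            raise DataError(f"year {year} outside series span")
        return DailySeries(
            self.station_id, self.dates[mask], self.tmax[mask], self.tmin[mask]
        )

    def period_slice(self, start_year: int, end_year: int) -> "DailySeries":
        mask = (self.dates.year >= start_year) & (self.dates.year <= end_year)
        if not mask.any():
            raise DataError(f"period {start_year}-{end_year} outside series span")
        return DailySeries(
            self.station_id, self.dates[mask], self.tmax[mask], self.tmin[mask]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates.strftime("%Y-%m-%d"), "tmax_c": self.tmax, "tmin_c": self.tmin}
        )


def write_series_csv(series: DailySeries, path: str | Path) -> Path:
    """Write one station to CSV (columns: date, tmax_c, tmin_c, ISO dates)."""
    path = Path(path)
    series.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


def read_series_csv(path: str | Path, station_id: str | None = None) -> DailySeries:
    path = Path(path)
    df = pd.read_csv(path, parse_dates=["date"])
    sid = station_id if station_id is not None else path.stem
    return DailySeries(sid, pd.DatetimeIndex(df["date"]), df["tmax_c"].to_numpy(), df["tmin_c"].to_numpy())


def write_catalogue_csv(stations: Sequence[StationSpec], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "station_id": [s.station_id for s in stations],
            "lon": [s.lon for s in stations],
            "lat": [s.lat for s in stations],
            "country": [s.country for s in stations],
        }
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def read_catalogue_csv(path: str | Path) -> list[StationSpec]:
    df = pd.read_csv(path)
    return [
        StationSpec(str(r.station_id), float(r.lon), float(r.lat), str(r.country))
        for r in df.itertuples(index=False)
    ]


def series_to_dataset(series_list: Sequence[DailySeries]):
    """Stack aligned station series into an xarray Dataset (time, station)."""
    import xarray as xr

    if not series_list:
        raise DataError("no series supplied")
    ref_dates = series_list[0].dates
    for s in series_list[1:]:
        if not s.dates.equals(ref_dates):
            raise DataError("all series must share the same dates")
    ds = xr.Dataset(
        {
            "tmax": (("time", "station"), np.column_stack([s.tmax for s in series_list])),
            "tmin": (("time", "station"), np.column_stack([s.tmin for s in series_list])),
        },
        coords={
            "time": ref_dates,
            "station": [s.station_id for s in series_list],
        },
    )
    ds["tmax"].attrs["units"] = "degC"
    ds["tmin"].attrs["units"] = "degC"
    return ds


def write_series_netcdf(series_list: Sequence[DailySeries], path: str | Path) -> Path:
    """Write aligned stations to one NetCDF file (NetCDF3 via scipy backend)."""
    path = Path(path)
    ds = series_to_dataset(series_list)
    # scipy engine: no external netCDF-C dependency needed
    ds.to_netcdf(path, engine="scipy")
    return path


def read_series_netcdf(path: str | Path) -> list[DailySeries]:
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    out = []
    dates = pd.DatetimeIndex(ds["time"].values)
    for i, sid in enumerate(ds["station"].values):
        out.append(
            DailySeries(
                str(sid),
                dates,
                ds["tmax"].values[:, i],
                ds["tmin"].values[:, i],
            )
        )
    ds.close()
    return out
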