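"""Mean-variance bias correction of model series, stratified by calendar
month, with bias/RMSE evaluation and equal-weight ("one model, one vote")
ensembling.

The correction is the affine map

    x_hat = mu_o + (sigma_o / sigma_m) * (x - mu_m)

with the four moments fitted per calendar month on the historical overlap
of reference and model, then applied unchanged to any period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .series import DailySeries

__all__ = [
    "BiasCorrectionParams",
    "fit_params",
    "apply_correction",
    "correct_series",
    "bias",
    "rmse",
    "ensemble_mean",
    "evaluation_table",
]


@dataclass(frozen=True)
class BiasCorrectionParams:
    """Per station x calendar-month moments driving the affine correction."""

    station_id: str
    month: int
    mu_o: float
    sigma_o: float
    mu_m: float
    sigma_m: float

    def __post_init__(self) -> None:
        if not (1 <= self.month <= 12):
            raise ConfigurationError(f"month must be 1-12, got {self.month}")
        if self.sigma_o <= 0 or self.sigma_m <= 0:
            raise DataError(
                f"non-positive standard deviation for month {self.month}"
            )


def fit_params(
    ref: DailySeries,
    model: DailySeries,
    overlap: tuple[int, int],
    variable: str = "tmax",
) -> dict[int, BiasCorrectionParams]:
    """Fit the four moments per calendar month over the overlap years.

    Uses sample standard deviation (ddof=1). Raises a degenerate-data
    error naming the month if any month has zero variance.
    """
    r = ref.period_slice(*overlap)
    m = model.period_slice(*overlap)
    if not r.dates.equals(m.dates):
        raise DataError("reference and model must share dates on the overlap")
    rv = r.values(variable)
    mv = m.values(variable)
    months = r.dates.month.to_numpy()
    out: dict[int, BiasCorrectionParams] = {}
    for month in range(1, 13):
        sel = months == month
        if not sel.any():
            raise DataError(f"no overlap data for month {month}")
        so = float(np.std(rv[sel], ddof=1))
        sm = float(np.std(mv[sel], ddof=1))
        if so == 0 or sm == 0:
            raise DataError(f"zero variance in month {month}")
        out[month] = BiasCorrectionParams(
            station_id=ref.station_id,
            month=month,
            mu_o=float(np.mean(rv[sel])),
            sigma_o=so,
            mu_m=float(np.mean(mv[sel])),
            sigma_m=sm,
        )
    return out


def apply_correction(
    x: float | np.ndarray,
    params: BiasCorrectionParams | Mapping[int, BiasCorrectionParams],
    months: np.ndarray | int | None = None,
) -> float | np.ndarray:
    """Elementwise x_hat = mu_o + (sigma_o/sigma_m)(x - mu_m).

    With a single ``BiasCorrectionParams`` the same month's parameters
    apply to every element; with a month->params mapping each value is
    corrected with its own calendar month's parameters (``months``
    required).
    """
    if isinstance(params, BiasCorrectionParams):
        p = params
        return p.mu_o + (p.sigma_o / p.sigma_m) * (np.asarray(x, dtype=float) - p.mu_m)
    if months is None:
        raise ConfigurationError("months required with per-month parameters")
    x = np.asarray(x, dtype=float)
    months = np.asarray(months)
    out = np.empty_like(x)
    for month in np.unique(months):
        if int(month) not in params:
            raise ConfigurationError(f"missing parameters for month {month}")
        p = params[int(month)]
        sel = months == month
        out[sel] = p.mu_o + (p.sigma_o / p.sigma_m) * (x[sel] - p.mu_m)
    return out


def correct_series(
    model: DailySeries,
    params_by_var: Mapping[str, Mapping[int, BiasCorrectionParams]],
) -> DailySeries:
    """Correct tmax and tmin of a model series with per-month parameters."""
    months = model.dates.month.to_numpy()
    corrected = {}
    for var in ("tmax", "tmin"):
        if var in params_by_var:
            corrected[var] = apply_correction(
                model.values(var), params_by_var[var], months
            )
        else:
            corrected[var] = model.values(var)
    tmax = np.asarray(corrected["tmax"])
    tmin = np.minimum(np.asarray(corrected["tmin"]), tmax)
    return DailySeries(
        model.station_id,
        model.dates,
        tmax,
        tmin,
        attrs={**model.attrs, "bias_corrected": True},
    )


def _check_pair(b: np.ndarray, o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(b, dtype=float)
    o = np.asarray(o, dtype=float)
    if b.shape != o.shape:
        raise DataError("model and reference vectors must have equal length")
    if b.size < 1:
        raise DataError("empty evaluation pair")
    return b, o


def bias(b: np.ndarray, o: np.ndarray) -> float:
    """Mean error (positive = model too warm)."""
    b, o = _check_pair(b, o)
    return float(np.mean(b - o))


def rmse(b: np.ndarray, o: np.ndarray) -> float:
    """Root-mean-square error; always >= |bias|."""
    b, o = _check_pair(b, o)
    return float(np.sqrt(np.mean((b - o) ** 2)))


def ensemble_mean(members: Sequence[DailySeries]) -> DailySeries:
    """Unweighted elementwise mean across member series."""
    if not members:
        raise DataError("ensemble requires >= 1 member")
    ref_dates = members[0].dates
    for m in members[1:]:
        if not m.dates.equals(ref_dates):
            raise DataError("ensemble members must share dates")
    tmax = np.mean([m.tmax for m in members], axis=0)
    tmin = np.mean([m.tmin for m in members], axis=0)
    return DailySeries(
        members[0].station_id,
        ref_dates,
        tmax,
        np.minimum(tmin, tmax),
        attrs={"ensemble_size": len(members)},
    )


def evaluation_table(
    ref: DailySeries,
    raw: DailySeries,
    corrected: DailySeries,
    period: tuple[int, int],
    variables: Sequence[str] = ("tmax", "tmin"),
) -> pd.DataFrame:
    """Per-month bias/RMSE of raw vs corrected model against reference."""
    r = ref.period_slice(*period)
    rows = []
    months = r.dates.month.to_numpy()
    for var in variables:
        o = r.values(var)
        bvals = raw.period_slice(*period).values(var)
        cvals = corrected.period_slice(*period).values(var)
        for month in range(1, 13):
            sel = months == month
            rows.append(
                {
                    "station": ref.station_id,
                    "month": month,
                    "variable": var,
                    "bias_raw": bias(bvals[sel], o[sel]),
                    "bias_corrected": bias(cvals[sel], o[sel]),
                    "rmse_raw": rmse(bvals[sel], o[sel]),
                    "rmse_corrected": rmse(cvals[sel], o[sel]),
                }
            )
    return pd.DataFrame(rows)
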