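"""Yearly heatwave-magnitude severity categories and heat-attributable
all-cause mortality.

Severity bins (degC, on yearly HWM):

    0            No heatwave
    (0, 12]      Below normal   (gap policy: sub-threshold magnitudes)
    (12, 23]     Normal
    (23, 31]     Moderate
    (31, 32]     Severe
    (32, 38]     Extreme
    (38, 40)     Very extreme   (gap policy: (39, 40) folded into this bin)
    [40, 50)     Super extreme
    [50, inf)    Ultra-extreme

Attributable mortality uses the attributable-fraction identity

    attributable = heatwave_days * death_daily * (RR - 1) / RR

with a pooled all-cause relative risk applied uniformly across countries
(default RR 1.20, 95% CI 1.02-1.41).
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "SeverityScheme",
    "DEFAULT_SCHEME",
    "RiskSpec",
    "DEFAULT_RISK",
    "classify_hwm",
    "regional_category",
    "daily_deaths",
    "attributable_mortality",
    "country_burden",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeverityScheme:
    """Ordered HWM bins with regional coverage quotas.

    ``bins`` are (label, lower, upper) with lower-exclusive / upper-
    inclusive semantics except the open-ended top bins. ``quotas`` map a
    label to the minimum fraction of stations whose yearly HWM must reach
    that label's lower bound for the region to carry the label.
    """

    bins: tuple[tuple[str, float, float], ...] = (
        ("Below normal", 0.0, 12.0),
        ("Normal", 12.0, 23.0),
        ("Moderate", 23.0, 31.0),
        ("Severe", 31.0, 32.0),
        ("Extreme", 32.0, 38.0),
        ("Very extreme", 38.0, 40.0),
        ("Super extreme", 40.0, 50.0),
        ("Ultra-extreme", 50.0, float("inf")),
    )
    quotas: Mapping[str, float] = field(
        default_factory=lambda: {
            "Normal": 1.00,
            "Moderate": 0.80,
            "Severe": 0.70,
            "Extreme": 0.30,
            "Very extreme": 0.03,
        }
    )
    no_event_label: str = "No heatwave"

    def order(self, label: str) -> int:
        if label == self.no_event_label:
            return -1
        for i, (name, _, _) in enumerate(self.bins):
            if name == label:
                return i
        raise ValueError(f"unknown label {label!r}")


DEFAULT_SCHEME = SeverityScheme()


def classify_hwm(
    hwm: float, scheme: SeverityScheme = DEFAULT_SCHEME, strict: bool = True
) -> str:
    """Map a yearly HWM value to its severity label.

    HWM = 0 means no heatwave; top bins are lower-inclusive (>= 40, >= 50)
    and the most severe applicable label wins. Negative magnitudes (events
    whose mean Tmax is below 0 degC, possible in cold climates) are a
    domain error when ``strict`` and fold into the lowest bin otherwise.
    """
    if not np.isfinite(hwm):
        raise ValueError(f"hwm must be finite, got {hwm}")
    if hwm < 0:
        if strict:
            raise ValueError(f"hwm must be >= 0, got {hwm}")
        return scheme.bins[0][0]
    if hwm == 0:
        return scheme.no_event_label
    # scan from most severe down: top bins are lower-INclusive (>= 40,
    # >= 50), bounded bins lower-EXclusive / upper-inclusive
    for label, low, _high in reversed(scheme.bins):
        if low >= 40.0:
            if hwm >= low:
                return label
        elif hwm > low:
            return label
    raise ValueError(f"no bin matched hwm={hwm}")  # pragma: no cover


def regional_category(
    hwm_by_station: Mapping[str, float],
    scheme: SeverityScheme = DEFAULT_SCHEME,
) -> tuple[str, list[str]]:
    """Most severe label whose coverage quota is met, plus all met labels.

    For each quota label, the coverage fraction is the share of stations
    whose yearly HWM is strictly above that label's lower bound.
    """
    if not hwm_by_station:
        raise DataError("empty station map")
    values = np.asarray(list(hwm_by_station.values()), dtype=float)
    met: list[str] = []
    for label, quota in scheme.quotas.items():
        low = next(lo for (name, lo, _) in scheme.bins if name == label)
        frac = float(np.mean(values > low))
        if frac >= quota:
            met.append(label)
    # quota-less top bins: carried when any station reaches them
    for label, low, _ in scheme.bins:
        if low >= 40.0 and np.any(values >= low):
            met.append(label)
    if not met:
        return scheme.no_event_label, []
    met.sort(key=scheme.order)
    return met[-1], met


def daily_deaths(annual_deaths: float, year: int) -> float:
    """Annual deaths spread evenly over 365 (or 366 in leap years) days."""
    if annual_deaths < 0:
        raise ValueError("annual_deaths must be >= 0")
    return annual_deaths / (366.0 if calendar.isleap(year) else 365.0)


def attributable_mortality(
    heatwave_days: float, death_daily: float, rr: float
) -> float:
    """heatwave_days * death_daily * (RR - 1) / RR."""
    if rr <= 0:
        raise ValueError("relative risk must be > 0")
    if heatwave_days < 0 or death_daily < 0:
        raise ValueError("heatwave_days and death_daily must be >= 0")
    if rr < 1:
        logger.warning("rr=%.3f < 1: attributable mortality is protective", rr)
    return heatwave_days * death_daily * (rr - 1.0) / rr


@dataclass(frozen=True)
class RiskSpec:
    """Pooled relative risk with its 95% confidence bounds."""

    rr: float = 1.20
    rr_low: float = 1.02
    rr_high: float = 1.41


DEFAULT_RISK = RiskSpec()


def country_burden(
    indices: pd.DataFrame,
    demography: pd.DataFrame,
    station_country: Mapping[str, str],
    risk: RiskSpec = DEFAULT_RISK,
    scenario: str = "historical",
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per country-year heatwave-attributable deaths (point + RR CI).

    ``heatwave_days`` aggregates HWF across the country's stations
    (default: mean over stations). Every station in ``indices`` must map
    to a country present in the demography table.
    """
    if aggregation not in ("mean", "sum"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    idx = indices.copy()
    unmapped = set(idx["station_id"]) - set(station_country)
    if unmapped:
        raise ConfigurationError(f"stations without a country: {sorted(unmapped)}")
    idx["country"] = idx["station_id"].map(station_country)
    agg = getattr(idx.groupby(["country", "year"])["hwf"], aggregation)()
    demog = demography.set_index(["country", "year"])

    rows = []
    for (country, year), hw_days in agg.items():
        try:
            rec = demog.loc[(country, year)]
        except KeyError:
            raise ConfigurationError(
                f"no demography row for {country} {year}"
            ) from None
        dd = daily_deaths(float(rec["annual_deaths"]), int(year))
        rows.append(
            {
                "country": country,
                "year": int(year),
                "scenario": scenario,
                "heatwave_days": float(hw_days),
                "death_daily": dd,
                "rr": risk.rr,
                "attributable": attributable_mortality(hw_days, dd, risk.rr),
                "attributable_low": attributable_mortality(hw_days, dd, risk.rr_low),
                "attributable_high": attributable_mortality(hw_days, dd, risk.rr_high),
            }
        )
    return pd.DataFrame(rows).sort_values(["country", "year"]).reset_index(drop=True)
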