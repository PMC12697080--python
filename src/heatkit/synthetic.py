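"""Synthetic reference ("pseudo-reanalysis") and model ("pseudo-GCM") data.

Every generator is deterministic under its seed and emits ground-truth
metadata (true trend, true bias, injected episode dates) in ``attrs`` so
downstream parameter-recovery tests have an oracle to compare against.

Randomness is consumed strictly chronologically, year by year, so a run
with a later ``end_year`` reproduces the earlier years bit-for-bit — the
historical slice of a 1959-2100 "scenario truth" equals the 1959-2021
reference exactly.
"""

from __future__ import annotations

import calendar
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError
from .series import DailySeries, StationSpec

__all__ = [
    "SyntheticConfig",
    "DEFAULT_BBOX",
    "COUNTRY_CODES",
    "generate_station_catalogue",
    "generate_reference_series",
    "generate_gcm_series",
    "generate_demography",
    "write_demography_csv",
]

#: lon_min, lon_max, lat_min, lat_max — a Central-Asia-like box
DEFAULT_BBOX = (46.0, 87.0, 35.0, 56.0)

COUNTRY_CODES = ("KAZ", "KGZ", "TJK", "TKM", "UZB")

# warm half-year window (calendar day-of-year, leap-indexed) for episode injection
_WARM_DOY_START = 121
_WARM_DOY_END = 273

_SEASONAL_PEAK_DOY = 197  # mid-July


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic weather/demography generator.

    ``trend`` applies up to ``trend_switch_year`` (inclusive); afterwards
    ``future_trend`` takes over (defaults to ``trend``), which is how
    scenario-dependent future warming is expressed.
    """

    n_stations: int = 20
    start_year: int = 1962
    end_year: int = 2021
    seasonal_amplitude: float = 15.0
    baseline_mean: float = 12.0
    trend: float = 0.03
    ar1_coeff: float = 0.7
    noise_sd: float = 2.0
    episode_rate: float = 1.0
    episode_boost: float = 5.0
    gcm_bias: float = 2.0
    gcm_var_inflation: float = 1.3
    gcm_noise_sd: float = 0.5
    seed: int = 0
    future_trend: float | None = None
    trend_switch_year: int | None = None
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ConfigurationError(
                f"end_year ({self.end_year}) < start_year ({self.start_year})"
            )
        if self.n_stations < 1:
            raise ConfigurationError("n_stations must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0 <= self.ar1_coeff < 1):
            raise ConfigurationError("ar1_coeff must be in [0, 1)")
        if self.gcm_var_inflation <= 0:
            raise ConfigurationError("gcm_var_inflation must be > 0")
        if self.episode_rate < 0:
            raise ConfigurationError("episode_rate must be >= 0")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _station_rng(seed: int, station_id: str, salt: int = 0) -> np.random.Generator:
    sid_hash = zlib.crc32(station_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, sid_hash, salt]))


def generate_station_catalogue(cfg: SyntheticConfig) -> list[StationSpec]:
    """Random station coordinates in the bounding box, 5 country labels."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCA7]))
    lon_min, lon_max, lat_min, lat_max = cfg.bbox
    stations = []
    for i in range(cfg.n_stations):
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        country = COUNTRY_CODES[i % len(COUNTRY_CODES)]
        stations.append(StationSpec(f"ST{i:03d}", round(lon, 4), round(lat, 4), country))
    return stations


def _yearly_trend_offset(year: int, cfg: SyntheticConfig) -> float:
    switch = cfg.trend_switch_year
    future = cfg.future_trend if cfg.future_trend is not None else cfg.trend
    if switch is None or year <= switch:
        return cfg.trend * (year - cfg.start_year)
    return cfg.trend * (switch - cfg.start_year) + future * (year - switch)


def generate_reference_series(spec: StationSpec, cfg: SyntheticConfig) -> DailySeries:
    """Gap-free daily Tmax/Tmin over [start_year, end_year].

    Tmax = baseline + seasonal cosine + per-year linear trend + AR(1)
    noise + injected multi-day warm episodes (warm half-year only);
    Tmin = Tmax minus a positive diurnal range.
    """
    rng = _station_rng(cfg.seed, spec.station_id)
    lat_adj = -0.2 * (spec.lat - 45.0)  # mild latitudinal gradient

    z_chunks: list[np.ndarray] = []
    dtr_chunks: list[np.ndarray] = []
    det_chunks: list[np.ndarray] = []
    episodes: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    boost_chunks: list[np.ndarray] = []

    for year in range(cfg.start_year, cfg.end_year + 1):
        ndays = 366 if calendar.isleap(year) else 365
        doy = np.arange(1, ndays + 1)
        seasonal = cfg.seasonal_amplitude * np.cos(
            2 * np.pi * (doy - _SEASONAL_PEAK_DOY) / ndays
        )
        det = cfg.baseline_mean + lat_adj + seasonal + _yearly_trend_offset(year, cfg)

        # chronological draw order per year: noise, diurnal range, episodes
        z_chunks.append(rng.standard_normal(ndays))
        dtr_chunks.append(np.maximum(0.5, 8.0 + 1.5 * rng.standard_normal(ndays)))

        boost = np.zeros(ndays)
        if cfg.episode_rate > 0:
            n_ep = rng.poisson(cfg.episode_rate)
            for _ in range(n_ep):
                dur = int(rng.integers(3, 8))
                start = int(rng.integers(_WARM_DOY_START, _WARM_DOY_END - dur + 2))
                boost[start - 1 : start - 1 + dur] += cfg.episode_boost
                t0 = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=start - 1)
                episodes.append((t0, t0 + pd.Timedelta(days=dur - 1)))
        det_chunks.append(det)
        boost_chunks.append(boost)

    z = np.concatenate(z_chunks)
    if cfg.noise_sd > 0 and cfg.ar1_coeff > 0:
        noise = lfilter(
            [np.sqrt(1 - cfg.ar1_coeff**2) * cfg.noise_sd],
            [1.0, -cfg.ar1_coeff],
            z,
        )
    else:
        noise = cfg.noise_sd * z

    tmax = np.concatenate(det_chunks) + np.concatenate(boost_chunks) + noise
    # episodes warm nights too, but less than days: diurnal range stays positive
    tmin = tmax - np.concatenate(dtr_chunks) + 0.0
    dates = pd.date_range(
        f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-31", freq="D"
    )
    return DailySeries(
        spec.station_id,
        dates,
        tmax,
        tmin,
        attrs={
            "true_trend": cfg.trend,
            "true_future_trend": cfg.future_trend if cfg.future_trend is not None else cfg.trend,
            "episodes": episodes,
            "config_seed": cfg.seed,
        },
    )


def generate_gcm_series(
    ref: DailySeries, cfg: SyntheticConfig, model_seed: int = 0
) -> DailySeries:
    """Pseudo-GCM run derived from a (possibly extended) reference series.

    model = mu_ref + gcm_var_inflation * (ref - mu_ref) + gcm_bias + noise,
    with mu_ref the per-variable mean of ``ref``. Ground-truth distortion
    parameters are stored in ``attrs`` for recovery tests.
    """
    rng = _station_rng(cfg.seed, ref.station_id, salt=1000 + model_seed)
    out = {}
    for var in ("tmax", "tmin"):
        x = ref.values(var)
        mu = float(np.mean(x))
        noise = (
            cfg.gcm_noise_sd * rng.standard_normal(len(x))
            if cfg.gcm_noise_sd > 0
            else 0.0
        )
        out[var] = mu + cfg.gcm_var_inflation * (x - mu) + cfg.gcm_bias + noise
    tmax = out["tmax"]
    tmin = np.minimum(out["tmin"], tmax)  # keep the physical ordering under noise
    return DailySeries(
        ref.station_id,
        ref.dates,
        tmax,
        tmin,
        attrs={
            "true_bias": cfg.gcm_bias,
            "true_var_inflation": cfg.gcm_var_inflation,
            "model_seed": model_seed,
            "source": ref.station_id,
        },
    )


def generate_demography(
    countries: Sequence[str], years: Sequence[int], seed: int
) -> pd.DataFrame:
    """Per country-year total deaths and population with a smooth trajectory.

    Population follows logistic growth toward a country-specific cap;
    deaths = declining crude rate x population with small multiplicative
    noise. One row per country-year.
    """
    countries = list(countries)
    years = list(years)
    if not countries or not years:
        raise ConfigurationError("countries and years must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE40]))
    rows = []
    y0, y1 = min(years), max(years)
    for country in countries:
        cap = rng.uniform(5e6, 4e7)
        p_start = cap * rng.uniform(0.15, 0.4)
        growth = rng.uniform(0.02, 0.05)
        mid = y0 + (y1 - y0) * rng.uniform(0.3, 0.7)
        rate0 = rng.uniform(9.0, 13.0)   # crude death rate per 1000, start
        rate1 = rng.uniform(6.0, 9.0)    # per 1000, end
        noise = rng.normal(0.0, 0.02, size=len(years))
        for j, year in enumerate(years):
            pop = cap / (1.0 + (cap / p_start - 1.0) * np.exp(-growth * (year - y0)))
            frac = (year - y0) / max(1, y1 - y0)
            rate = rate0 + (rate1 - rate0) * frac
            deaths = max(0, int(round(rate / 1000.0 * pop * (1.0 + noise[j]))))
            rows.append(
                {
                    "country": country,
                    "year": year,
                    "annual_deaths": deaths,
                    "population": int(round(pop)),
                }
            )
    return pd.DataFrame(rows)


def write_demography_csv(demog: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    demog.to_csv(path, index=False)
    return path
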