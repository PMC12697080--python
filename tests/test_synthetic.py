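import calendar

import numpy as np
import pandas as pd
import pytest

from heatkit.errors import ConfigurationError
from heatkit.indices import calendar_day_percentile, detect_heatwaves
from heatkit.series import StationSpec
from heatkit.synthetic import (
    SyntheticConfig,
    generate_demography,
    generate_gcm_series,
    generate_reference_series,
    generate_station_catalogue,
)
from heatkit.trends import sens_slope

from oracles import ols_slope


def annual_means(series, variable="tmax"):
    return (
        pd.Series(series.values(variable), index=series.dates)
        .groupby(series.dates.year)
        .mean()
    )


class TestReferenceSeries:
    def test_seed_determinism(self, station, small_cfg):
        a = generate_reference_series(station, small_cfg)
        b = generate_reference_series(station, small_cfg)
        assert np.array_equal(a.tmax, b.tmax)
        assert np.array_equal(a.tmin, b.tmin)

    def test_no_signal_limit(self, station):
        # non-leap first/last years so the seasonal sum is identical
        cfg = SyntheticConfig(
            start_year=1959,
            end_year=2021,
            trend=0.0,
            noise_sd=0.0,
            episode_rate=0.0,
            seed=1,
        )
        s = generate_reference_series(station, cfg)
        means = annual_means(s)
        assert abs(means.loc[1959] - means.loc[2021]) < 1e-6

    def test_trend_recovery_sens_slope(self, station):
        # oracle: OLS on annual means should agree with Sen's slope
        slopes, ols = [], []
        for seed in range(100):
            cfg = SyntheticConfig(
                start_year=1962,
                end_year=2021,
                trend=0.05,
                noise_sd=1.0,
                episode_rate=0.0,
                seed=seed,
            )
            y = annual_means(generate_reference_series(station, cfg)).to_numpy()
            slopes.append(sens_slope(y))
            ols.append(ols_slope(y))
        mean_slope = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean_slope - 0.05) <= 1.96 * se + 1e-3
        assert abs(np.mean(ols) - 0.05) <= 1.96 * np.std(ols, ddof=1) / 10 + 1e-3

    def test_calendar_completeness(self, station, small_cfg):
        s = generate_reference_series(station, small_cfg)
        counts = pd.Series(1, index=s.dates).groupby(s.dates.year).sum()
        for year, n in counts.items():
            assert n == (366 if calendar.isleap(year) else 365)

    def test_tmax_ge_tmin(self, station, small_cfg):
        s = generate_reference_series(station, small_cfg)
        assert np.all(s.tmax >= s.tmin)

    def test_invalid_year_range(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(start_year=2020, end_year=2019)

    def test_episode_ground_truth_recorded(self, station):
        cfg = SyntheticConfig(
            start_year=2001, end_year=2005, episode_rate=2.0, seed=3
        )
        s = generate_reference_series(station, cfg)
        assert len(s.attrs["episodes"]) > 0
        for t0, t1 in s.attrs["episodes"]:
            assert (t1 - t0).days >= 2  # >= 3-day runs


class TestEpisodeRecoverability:
    def test_detector_finds_injected_episodes(self, station):
        # 100-seed average recovery with strong boost and weak noise
        rates = []
        for seed in range(100):
            cfg = SyntheticConfig(
                start_year=2001,
                end_year=2015,
                episode_boost=6.0,
                noise_sd=1.0,
                episode_rate=1.0,
                trend=0.0,
                seed=seed,
            )
            s = generate_reference_series(station, cfg)
            episodes = s.attrs["episodes"]
            if not episodes:
                continue
            clim = calendar_day_percentile(s, "tmax")
            events = []
            for year in s.years:
                events.extend(detect_heatwaves(s, clim, int(year), 3))
            hit = 0
            for t0, t1 in episodes:
                if any(ev.start_date <= t1 and ev.end_date >= t0 for ev in events):
                    hit += 1
            rates.append(hit / len(episodes))
        assert np.mean(rates) >= 0.90


class TestGcmSeries:
    def test_identity_settings(self, station, small_cfg):
        ref = generate_reference_series(station, small_cfg)
        cfg = small_cfg.with_(gcm_bias=0.0, gcm_var_inflation=1.0, gcm_noise_sd=0.0)
        g = generate_gcm_series(ref, cfg)
        np.testing.assert_allclose(g.tmax, ref.tmax, atol=1e-12)
        np.testing.assert_allclose(g.tmin, ref.tmin, atol=1e-12)

    def test_injected_bias_recovered(self, station):
        cfg = SyntheticConfig(start_year=1962, end_year=2021, seed=5, gcm_bias=3.0)
        ref = generate_reference_series(station, cfg)
        g = generate_gcm_series(ref, cfg)
        assert abs((g.tmax.mean() - ref.tmax.mean()) - 3.0) < 0.1

    def test_variance_inflation_recovered(self, station, small_cfg):
        cfg = small_cfg.with_(gcm_var_inflation=2.0, gcm_noise_sd=0.0, gcm_bias=0.0)
        ref = generate_reference_series(station, cfg)
        g = generate_gcm_series(ref, cfg)
        ratio = np.std(g.tmax) / np.std(ref.tmax)
        assert abs(ratio - 2.0) / 2.0 < 0.05

    def test_ground_truth_attrs(self, station, small_cfg):
        ref = generate_reference_series(station, small_cfg)
        g = generate_gcm_series(ref, small_cfg.with_(gcm_bias=1.5))
        assert g.attrs["true_bias"] == 1.5

    def test_gcm_determinism(self, station, small_cfg):
        ref = generate_reference_series(station, small_cfg)
        a = generate_gcm_series(ref, small_cfg, model_seed=2)
        b = generate_gcm_series(ref, small_cfg, model_seed=2)
        assert np.array_equal(a.tmax, b.tmax)


class TestCatalogue:
    def test_within_bbox_and_unique(self, small_cfg):
        cat = generate_station_catalogue(small_cfg)
        lon0, lon1, lat0, lat1 = small_cfg.bbox
        ids = [s.station_id for s in cat]
        assert len(set(ids)) == len(ids) == small_cfg.n_stations
        for s in cat:
            assert lon0 <= s.lon <= lon1
            assert lat0 <= s.lat <= lat1


class TestDemography:
    def test_row_count(self):
        t = generate_demography(["KAZ"], [2000, 2001, 2002], seed=1)
        assert len(t) == 3

    def test_positivity(self):
        t = generate_demography(["KAZ", "UZB"], range(1990, 2050), seed=9)
        assert (t["annual_deaths"] >= 0).all()
        assert (t["population"] > 0).all()

    def test_seed_determinism(self):
        a = generate_demography(["KAZ", "KGZ"], range(2000, 2010), seed=4)
        b = generate_demography(["KAZ", "KGZ"], range(2000, 2010), seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_inputs_error(self):
        with pytest.raises(ConfigurationError):
            generate_demography([], range(2000, 2010), seed=1)
        with pytest.raises(ConfigurationError):
            generate_demography(["KAZ"], [], seed=1)
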