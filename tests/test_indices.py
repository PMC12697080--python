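import numpy as np
import pandas as pd
import pytest

from heatkit.errors import DataError
from heatkit.indices import (
    ThresholdClimatology,
    calendar_day_index,
    calendar_day_percentile,
    detect_heatwaves,
    indices_table,
    read_indices_csv,
    warm_day_fraction,
    write_indices_csv,
    yearly_indices,
)
from heatkit.series import DailySeries

from conftest import flat_clim, make_series
from oracles import naive_heatwave_scan, type7_percentile


def constant_series(value, start_year=2001, end_year=2002, station_id="C"):
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    v = np.full(len(dates), float(value))
    return DailySeries(station_id, dates, v, v - 10.0)


class TestCalendarDayIndex:
    def test_leap_alignment(self):
        dates = pd.DatetimeIndex(["2001-03-01", "2004-03-01", "2004-02-29"])
        idx = calendar_day_index(dates)
        assert idx[0] == idx[1] == 61
        assert idx[2] == 60


class TestCalendarDayPercentile:
    def test_constant_series(self):
        clim = calendar_day_percentile(constant_series(20.0))
        assert np.all(clim.thresholds == 20.0)
        assert clim.thresholds.shape == (366,)

    def test_brute_force_oracle(self):
        # 2 years, window_halfwidth=2: threshold = type-7 p90 of 10 pooled
        # values, computed independently by manual sort-and-interpolate
        rng = np.random.default_rng(0)
        s = constant_series(0.0)
        s = DailySeries(
            "R", s.dates, rng.normal(20, 5, len(s.dates)), np.full(len(s.dates), 0.0)
        )
        clim = calendar_day_percentile(s, "tmax", (2001, 2002), 90.0, 2)
        cal = calendar_day_index(s.dates)
        for d in [1, 60, 100, 366]:
            members = [((d - 1) + k) % 366 + 1 for k in range(-2, 3)]
            pool = s.tmax[np.isin(cal, members)]
            assert clim.thresholds[d - 1] == pytest.approx(
                type7_percentile(pool.tolist(), 90.0), abs=1e-12
            )

    def test_median_of_alternating_series(self):
        # +-1 degC alternation around a 20 degC midline; odd year length
        # flips parity between the two years so windows pool equal counts
        dates = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        v = 20.0 + np.where(np.arange(len(dates)) % 2 == 0, 1.0, -1.0)
        s = DailySeries("A", dates, v, v - 10)
        clim = calendar_day_percentile(s, "tmax", q=50.0, window_halfwidth=7)
        np.testing.assert_allclose(clim.thresholds, 20.0, atol=1e-12)

    def test_base_period_not_covered(self):
        with pytest.raises(DataError):
            calendar_day_percentile(constant_series(20.0), base_period=(1990, 2002))

    def test_window_wraps_year_boundary(self):
        # Jan-1 window must include late-December values
        s = constant_series(0.0)
        tmax = s.tmax.copy()
        dec31 = (s.dates.month == 12) & (s.dates.day == 31)
        tmax[dec31] = 100.0
        s = DailySeries("W", s.dates, tmax, tmax - 10)
        clim = calendar_day_percentile(s, "tmax", q=90.0, window_halfwidth=2)
        assert clim.thresholds[0] > 0.0  # pulled up by the wrapped maxima


class TestWarmDayFraction:
    def test_all_below(self):
        s = constant_series(10.0)
        assert warm_day_fraction(s, flat_clim(20.0), 2001) == 0.0

    def test_all_above(self):
        s = constant_series(30.0)
        assert warm_day_fraction(s, flat_clim(20.0), 2001) == 100.0

    def test_strict_exceedance(self):
        s = constant_series(20.0)
        assert warm_day_fraction(s, flat_clim(20.0), 2001) == 0.0

    def test_year_outside_series(self):
        with pytest.raises(DataError):
            warm_day_fraction(constant_series(10.0), flat_clim(20.0), 1999)


class TestDetectHeatwaves:
    def test_worked_example_min3(self, toy_series):
        events = detect_heatwaves(toy_series, flat_clim(30.0), 2001, 3)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_date == pd.Timestamp("2001-01-03")
        assert ev.end_date == pd.Timestamp("2001-01-06")
        assert ev.duration == 4
        assert ev.peak == 33.0
        assert ev.mean_intensity == pytest.approx(31.75)

    def test_worked_example_min2(self, toy_series):
        events = detect_heatwaves(toy_series, flat_clim(30.0), 2001, 2)
        assert [(e.duration) for e in events] == [4, 2]
        assert events[1].start_date == pd.Timestamp("2001-01-08")

    def test_all_below(self, toy_series):
        assert detect_heatwaves(toy_series, flat_clim(40.0), 2001, 3) == []

    def test_year_boundary_attribution(self):
        # 6-day run over Dec 29 - Jan 3: one event, start year, full length
        dates = pd.date_range("2001-12-01", "2002-01-31", freq="D")
        v = np.full(len(dates), 20.0)
        v[(dates >= "2001-12-29") & (dates <= "2002-01-03")] = 35.0
        s = DailySeries("Y", dates, v, v - 10)
        ev_2001 = detect_heatwaves(s, flat_clim(30.0), 2001, 3)
        ev_2002 = detect_heatwaves(s, flat_clim(30.0), 2002, 3)
        assert len(ev_2001) == 1 and ev_2001[0].duration == 6
        assert ev_2002 == []

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(11)
        clim = flat_clim(0.0)
        for _ in range(100):
            n = 365
            tmax = rng.normal(0, 3, n)
            thr = np.zeros(n)
            s = make_series(tmax, start="2003-01-01")
            got = detect_heatwaves(s, clim, 2003, 3)
            want = naive_heatwave_scan(tmax.tolist(), thr.tolist(), 3)
            assert len(got) == len(want)
            for ev, (s0, e0, dur, peak, mean) in zip(got, want):
                assert (ev.start_date - s.dates[0]).days == s0
                assert ev.duration == dur
                assert ev.peak == pytest.approx(peak)
                assert ev.mean_intensity == pytest.approx(mean)

    def test_monotone_in_min_duration(self):
        rng = np.random.default_rng(5)
        s = make_series(rng.normal(0, 3, 365), start="2003-01-01")
        clim = flat_clim(0.0)
        prev_hwn = prev_hwf = np.inf
        for md in (1, 2, 3, 5, 8):
            events = detect_heatwaves(s, clim, 2003, md)
            hwn = len(events)
            hwf = sum(e.duration for e in events)
            assert hwn <= prev_hwn and hwf <= prev_hwf
            prev_hwn, prev_hwf = hwn, hwf


class TestYearlyIndices:
    def test_worked_example(self, toy_series):
        clim = flat_clim(30.0)
        clim_tn = flat_clim(20.0, variable="tmin")
        yi = yearly_indices(toy_series, clim, clim_tn, 2001, 3)
        assert (yi.hwn, yi.hwf, yi.hwd) == (1, 4, 4)
        assert yi.hwm == pytest.approx(31.75)
        assert yi.hwa == 33.0

    def test_no_events(self, toy_series):
        yi = yearly_indices(
            toy_series, flat_clim(40.0), flat_clim(30.0, "tmin"), 2001, 3
        )
        assert (yi.hwn, yi.hwf, yi.hwd) == (0, 0, 0)
        assert yi.hwm == 0.0
        assert np.isnan(yi.hwa)

    def test_two_events(self):
        v = [20] * 3 + [31] * 3 + [20] * 3 + [32] * 5 + [20] * 3
        s = make_series(v)
        yi = yearly_indices(s, flat_clim(30.0), flat_clim(20.0, "tmin"), 2001, 3)
        assert (yi.hwn, yi.hwf, yi.hwd) == (2, 8, 5)

    def test_invariants_on_random_series(self, base_series):
        clim_tx = calendar_day_percentile(base_series, "tmax")
        clim_tn = calendar_day_percentile(base_series, "tmin")
        for year in base_series.years[:10]:
            yi = yearly_indices(base_series, clim_tx, clim_tn, int(year))
            assert 0 <= yi.tx90p <= 100 and 0 <= yi.tn90p <= 100
            assert yi.hwf >= yi.hwd
            assert (yi.hwn == 0) == (yi.hwf == 0)
            if yi.hwn > 0:
                assert yi.hwf >= 3 * yi.hwn
                assert yi.hwa >= yi.hwm

    def test_threshold_shift_monotonicity(self, base_series):
        clim_tx = calendar_day_percentile(base_series, "tmax")
        clim_tn = calendar_day_percentile(base_series, "tmin")
        shifted = ThresholdClimatology(
            "tmax",
            clim_tx.base_start,
            clim_tx.base_end,
            clim_tx.window_halfwidth,
            clim_tx.q,
            clim_tx.thresholds + 1.0,
        )
        for year in base_series.years[:8]:
            a = yearly_indices(base_series, clim_tx, clim_tn, int(year))
            b = yearly_indices(base_series, shifted, clim_tn, int(year))
            assert b.tx90p <= a.tx90p
            assert b.hwn <= a.hwn and b.hwf <= a.hwf and b.hwd <= a.hwd


class TestIndicesIO:
    def test_csv_round_trip_missing_hwa(self, toy_series, tmp_path):
        tab = indices_table(
            toy_series, flat_clim(40.0), flat_clim(30.0, "tmin"), [2001]
        )
        path = write_indices_csv(tab, tmp_path / "idx.csv")
        text = path.read_text()
        assert text.splitlines()[0].endswith(
            "tx90p,tn90p,hwn,hwf,hwd,hwm,hwa"
        )
        assert text.splitlines()[1].endswith(",")  # hwa empty field
        back = read_indices_csv(path)
        assert np.isnan(back["hwa"].iloc[0])
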