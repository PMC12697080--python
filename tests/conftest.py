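from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatkit.indices import ThresholdClimatology
from heatkit.series import DailySeries, StationSpec
from heatkit.synthetic import SyntheticConfig, generate_reference_series


@pytest.fixture
def station():
    return StationSpec("ST000", 70.0, 45.0, "KAZ")


@pytest.fixture
def small_cfg():
    return SyntheticConfig(
        n_stations=3, start_year=2001, end_year=2010, seed=42
    )


@pytest.fixture(scope="session")
def base_series():
    """One 30-year reference series shared across read-only tests."""
    cfg = SyntheticConfig(n_stations=1, start_year=1991, end_year=2020, seed=7)
    return generate_reference_series(StationSpec("S1", 70.0, 45.0, "KAZ"), cfg)


def make_series(tmax, start="2001-01-01", station_id="T", tmin_offset=10.0):
    """DailySeries from explicit tmax values (tmin = tmax - offset)."""
    tmax = np.asarray(tmax, dtype=float)
    dates = pd.date_range(start, periods=len(tmax), freq="D")
    return DailySeries(station_id, dates, tmax, tmax - tmin_offset)


def flat_clim(value, variable="tmax", q=90.0):
    """Climatology with the same threshold on every calendar day."""
    return ThresholdClimatology(
        variable, 2001, 2001, 0, q, np.full(366, float(value))
    )


@pytest.fixture
def toy_series():
    """The 10-day worked example series."""
    return make_series([28, 29, 31, 32, 33, 31, 28, 31, 31, 28])
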