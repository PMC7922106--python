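import numpy as np
import pytest

from phenoyield.prep import DailySeries
from phenoyield.synthetic import (DoubleLogisticParams, double_logistic,
                                  simulate_pixel_curve)


@pytest.fixture
def season_params():
    """A typical corn season: green-up mid June, senescence early September."""
    return DoubleLogisticParams(base=0.2, amplitude=0.6, rise_midpoint=160,
                                rise_rate=0.15, fall_midpoint=250,
                                fall_rate=0.12)


@pytest.fixture
def daily_curve(season_params):
    """Noise-free daily NDVI for the typical season on a full calendar year."""
    day = np.arange(1, 366)
    return DailySeries("px", 2015, day,
                       simulate_pixel_curve(season_params, day))


@pytest.fixture
def triangle_series():
    """Symmetric triangle peaking at DOY 200 over [150, 250]."""
    day = np.arange(150, 251)
    ndvi = np.where(day <= 200, 0.2 + 0.014 * (day - 150),
                    0.9 - 0.014 * (day - 200))
    return DailySeries("tri", 2015, day, ndvi)


def logistic_series(a, b, c, d, days):
    """Exact single-logistic samples, NDVI = c/(1+exp(a+b t)) + d."""
    days = np.asarray(days, dtype=float)
    return c / (1.0 + np.exp(a + b * days)) + d


@pytest.fixture
def curve_fn(season_params):
    return lambda t: double_logistic(t, season_params)
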