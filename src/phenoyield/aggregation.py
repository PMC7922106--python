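"""Corn-pixel selection and county-level NDVI aggregation.

Only pixels whose corn area fraction exceeds a purity threshold (default
70%, strict inequality) contribute to a county series.  Selected pixels
are combined by a corn-fraction-weighted average on the phenologically
adjusted time axis: each pixel enters with day 0 at its own season start,
and the county series runs to the shortest contributing season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .prep import DailySeries

__all__ = ["PixelWeight", "select_corn_pixels", "county_weighted_ndvi"]


@dataclass(frozen=True)
class PixelWeight:
    """Corn area fraction of one pixel in one county-year."""

    pixel_id: object
    county_id: object
    year: int
    corn_fraction: float

    def __post_init__(self):
        if not 0.0 <= self.corn_fraction <= 1.0:
            raise InvalidInputError("corn_fraction must be in [0, 1]")


def select_corn_pixels(weights, threshold: float = 0.70) -> list:
    """Pixel ids whose corn fraction is strictly greater than ``threshold``.

    ``weights`` is an iterable of :class:`PixelWeight` for one county-year
    (selection is per year, because crop maps change annually).  An empty
    selection is returned with a warning; the caller drops the county-year.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError("threshold must be in (0, 1)")
    selected = [w.pixel_id for w in weights if w.corn_fraction > threshold]
    if not selected:
        warnings.warn("no pixel above the corn purity threshold; "
                      "county-year will be dropped")
    return selected


def county_weighted_ndvi(pixel_series: list[DailySeries], weights: list[float],
                         county_id=None) -> DailySeries:
    """Corn-fraction-weighted mean of adjusted pixel series.

    All series must be on the adjusted axis (day 0 = own season start) and
    belong to one county-year.  The output covers day 0 to the shortest
    series' last day; each day's value is sum(w_i * ndvi_i) / sum(w_i).
    Scaling all weights by a constant leaves the result unchanged.
    """
    if len(pixel_series) == 0:
        raise InvalidInputError("no pixel series to aggregate")
    if len(weights) != len(pixel_series):
        raise InvalidInputError("one weight per pixel series required")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise InvalidInputError("weights must be positive")
    years = {s.year for s in pixel_series}
    if len(years) > 1:
        raise InvalidInputError(f"series span several years: {sorted(years)}")
    if any(s.day[0] != 0 for s in pixel_series):
        raise InvalidInputError("pixel series must be phenologically adjusted "
                                "(day index starting at 0)")
    n = min(len(s) for s in pixel_series)
    stack = np.vstack([s.ndvi[:n] for s in pixel_series])
    mean = (w[:, None] * stack).sum(axis=0) / w.sum()
    return DailySeries(county_id, pixel_series[0].year, np.arange(n), mean)
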