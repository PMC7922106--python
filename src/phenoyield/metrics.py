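"""Phenological metrics and the maximum-correlation NDVI predictor.

Each growth phase GP contributes two predictors:

* ``Duration = GPend - GPstart`` (days),
* ``Rate = (NDVI_GPend - NDVI_GPstart) / Duration`` (ΔNDVI per day),

so rate x duration reconstructs the NDVI change across the phase exactly.
The ninth predictor, Max-R², is the NDVI value at the days-since-SD index
whose across-sample correlation with county yield is maximal; the scan
starts at the season start (day 0 of the adjusted axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ModelingError
from .phenology import GrowthPhase

__all__ = ["duration", "rate", "metrics_from_phases",
           "MaxR2Selection", "select_max_r2"]


def duration(phase: GrowthPhase) -> float:
    """Phase length in days, GPend - GPstart (strictly positive)."""
    d = phase.gp_end - phase.gp_start
    if d <= 0:
        raise InvalidInputError(f"{phase.label}: non-positive duration {d}")
    return float(d)


def rate(phase: GrowthPhase) -> float:
    """NDVI change per day across the phase."""
    return (phase.ndvi_end - phase.ndvi_start) / duration(phase)


def metrics_from_phases(phases: list[GrowthPhase]) -> dict:
    """The eight duration/rate metrics keyed gp1d, gp1r, ..., gp4d, gp4r."""
    out = {}
    for ph in phases:
        key = ph.label.lower()
        out[key + "d"] = duration(ph)
        out[key + "r"] = rate(ph)
    return out


@dataclass(frozen=True)
class MaxR2Selection:
    """Outcome of the Max-R² day scan for one sample group.

    ``selected_day`` attains the maximum of ``profile`` (ties broken toward
    the earliest day, favouring earlier in-season prediction);
    ``values`` carries each county-year's NDVI at the selected day.
    """

    selected_day: int
    profile: pd.Series            # adjusted day -> cross-sample R^2
    n_samples: int
    values: pd.DataFrame          # county_id, year, maxr2_ndvi

    def __post_init__(self):
        if not np.isclose(self.profile.loc[self.selected_day],
                          self.profile.max()):
            raise ModelingError("selected day does not attain the profile maximum")


def select_max_r2(county_series: pd.DataFrame, yields: pd.DataFrame,
                  stride: int = 1, min_samples: int = 3,
                  yield_col: str = "yield_kg_ha") -> MaxR2Selection:
    """Scan adjusted days for the NDVI most correlated with yield.

    ``county_series`` is long-format (county_id, year, adj_day, ndvi) on
    the adjusted axis; ``yields`` has one row per county-year.  For every
    day present in all samples the cross-sample R² of yield on NDVI(day)
    is computed; the earliest argmax wins.  ``stride`` > 1 scans every
    k-th day (e.g. 8 to mimic the native composite step).
    """
    wide = county_series.pivot_table(index=["county_id", "year"],
                                     columns="adj_day", values="ndvi")
    wide = wide.dropna(axis=1)          # days common to all samples
    merged = wide.join(
        yields.set_index(["county_id", "year"])[yield_col], how="inner").dropna()
    if merged.shape[1] <= 1 or merged.shape[0] < min_samples:
        raise ModelingError(
            f"Max-R² scan needs >= {min_samples} samples on a common day grid")
    y = merged[yield_col].to_numpy(dtype=float)
    days = np.asarray([c for c in merged.columns if c != yield_col], dtype=int)
    days = days[np.argsort(days)][::max(1, int(stride))] if stride != 1 \
        else np.sort(days)
    x = merged[list(days)].to_numpy(dtype=float)

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * yc[:, None]).sum(axis=0) / denom, 0.0)
    profile = pd.Series(r ** 2, index=days)
    sel = int(days[int(np.argmax(profile.to_numpy()))])
    values = merged[[sel]].rename(columns={sel: "maxr2_ndvi"}).reset_index()
    return MaxR2Selection(selected_day=sel, profile=profile,
                          n_samples=len(merged), values=values)
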