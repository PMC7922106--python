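"""Stage-date extraction from a county-level daily NDVI series.

Five stage dates bound four growth phases:

====  =========================  ==========================================
date  corn stage                 how it is extracted
====  =========================  ==========================================
V1    emergence                  dynamic threshold: first day the rising
                                 limb exceeds the SD value by 10% of the
                                 SD-to-maximum range
V6    jointing                   inflection (-a/b) of a logistic fitted to
                                 the rising limb
VT    tasseling                  90% dynamic threshold on the rising limb
R4    dough                      first day the falling limb drops 10% of
                                 the maximum-to-ED range below the maximum
R6    maturity                   inflection of a logistic fitted to the
                                 falling limb
====  =========================  ==========================================

GP1 = [V1, V6], GP2 = [V6, VT], GP3 = [VT, R4], GP4 = [R4, R6].

Threshold crossings are located with linear interpolation between adjacent
days and rounded half-up to whole days.  The piecewise logistic
``NDVI(t) = c / (1 + exp(a + b t)) + d`` is fitted per limb by bounded
nonlinear least squares (b < 0 rising, b > 0 descending); its derivative
is maximal in magnitude at t = -a/b, which is why the inflection dates
come straight from the fitted parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import (InvalidInputError, LogisticFitError,
                     PhenologyExtractionError)
from .prep import DailySeries, GrowingSeason

__all__ = [
    "PhenoDates",
    "LogisticFit",
    "GrowthPhase",
    "extract_threshold_dates",
    "fit_piecewise_logistic",
    "extract_inflection_dates",
    "build_growth_phases",
    "extract_phenology",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class PhenoDates:
    """The five stage dates, ordered V1 <= V6 <= VT <= R4 <= R6."""

    v1: int
    v6: int
    vt: int
    r4: int
    r6: int

    def __post_init__(self):
        seq = (self.v1, self.v6, self.vt, self.r4, self.r6)
        if not all(a <= b for a, b in zip(seq, seq[1:])):
            raise InvalidInputError(f"stage dates out of order: {seq}")

    def as_dict(self) -> dict:
        return {"v1": self.v1, "v6": self.v6, "vt": self.vt,
                "r4": self.r4, "r6": self.r6}


@dataclass(frozen=True)
class LogisticFit:
    """One fitted limb of the piecewise logistic.

    ``NDVI(t) = c / (1 + exp(a + b*t)) + d``; the rising limb has b < 0,
    the descending limb b > 0; c > 0 in both.
    """

    branch: str                # "rising" | "descending"
    a: float
    b: float
    c: float
    d: float
    window: tuple              # (first day, last day) of the fit
    rmse: float

    @property
    def midpoint(self) -> float:
        """Day of the inflection (extremum of the derivative), -a/b."""
        return -self.a / self.b

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.c / (1.0 + np.exp(self.a + self.b * t)) + self.d


@dataclass(frozen=True)
class GrowthPhase:
    """One growth phase with its boundary days and NDVI values."""

    label: str
    gp_start: float
    gp_end: float
    ndvi_start: float
    ndvi_end: float

    def __post_init__(self):
        if self.gp_start >= self.gp_end:
            raise PhenologyExtractionError(
                f"{self.label}: start {self.gp_start} not before end {self.gp_end}")


def _first_crossing_up(day, y, start_idx, stop_idx, level) -> float:
    """First fractional day in [start, stop] where y rises through level."""
    for i in range(start_idx, stop_idx + 1):
        if y[i] >= level:
            if i == start_idx or y[i] == y[i - 1]:
                return float(day[i])
            frac = (level - y[i - 1]) / (y[i] - y[i - 1])
            return float(day[i - 1] + frac)
    raise PhenologyExtractionError(f"threshold {level:.4f} never crossed")


def _first_crossing_down(day, y, start_idx, stop_idx, level) -> float:
    for i in range(start_idx, stop_idx + 1):
        if y[i] <= level:
            if i == start_idx or y[i] == y[i - 1]:
                return float(day[i])
            frac = (y[i - 1] - level) / (y[i - 1] - y[i])
            return float(day[i - 1] + frac)
    raise PhenologyExtractionError(f"threshold {level:.4f} never crossed")


def extract_threshold_dates(series: DailySeries, season: GrowingSeason,
                            lower_frac: float = 0.10,
                            upper_frac: float = 0.90) -> tuple[int, int, int]:
    """Dynamic-threshold dates (V1, VT, R4).

    V1 and VT are the days the rising limb first exceeds the SD value by
    10% and 90% of the SD-to-maximum range; R4 is the first day the falling
    limb drops below the maximum by 10% of the maximum-to-ED range.
    """
    day, y = series.day, series.ndvi
    i_sd = int(np.searchsorted(day, season.sd))
    i_ed = int(np.searchsorted(day, season.ed))
    if day[i_sd] != season.sd or day[i_ed] != season.ed:
        raise InvalidInputError("season bounds must be days of the series")
    i_peak = i_sd + int(np.argmax(y[i_sd:i_ed + 1]))
    y_sd, y_ed, y_max = y[i_sd], y[i_ed], y[i_peak]
    if (y_max - y_sd) <= 1e-9 or (y_max - y_ed) <= 1e-9:
        raise PhenologyExtractionError("degenerate amplitude; no stage dates")
    v1 = _first_crossing_up(day, y, i_sd, i_peak,
                            y_sd + lower_frac * (y_max - y_sd))
    vt = _first_crossing_up(day, y, i_sd, i_peak,
                            y_sd + upper_frac * (y_max - y_sd))
    r4 = _first_crossing_down(day, y, i_peak, i_ed,
                              y_max - lower_frac * (y_max - y_ed))
    return round_half_up(v1), round_half_up(vt), round_half_up(r4)


def _logistic(t, a, b, c, d):
    return c / (1.0 + np.exp(np.clip(a + b * t, -500, 500))) + d


def _logistic_jac(t, a, b, c, d):
    e = np.exp(np.clip(a + b * t, -500, 500))
    denom = (1.0 + e) ** 2
    da = -c * e / denom
    return np.column_stack([da, t * da, 1.0 / (1.0 + e), np.ones_like(t)])


def _fit_branch(day: np.ndarray, y: np.ndarray, branch: str) -> LogisticFit:
    if len(day) < 6:
        raise LogisticFitError(f"{branch} limb has fewer than 6 points",
                               branch=branch)
    d0 = float(np.min(y))
    c0 = float(np.max(y) - np.min(y))
    if c0 <= 1e-6:
        raise LogisticFitError(f"{branch} limb is flat (c ~ 0)", branch=branch)
    half = d0 + 0.5 * c0
    rising = branch == "rising"
    yy = y if rising else y[::-1]
    dd = day if rising else day[::-1]
    t_m = float(np.interp(half, yy, dd)) if rising else \
        float(np.interp(half, y[::-1], day[::-1]))
    # secant slope around the half-crossing; model slope there is -b*c/4
    h = max(1.0, (day[-1] - day[0]) / 10.0)
    s = (np.interp(t_m + h, day, y) - np.interp(t_m - h, day, y)) / (2 * h)
    b0 = float(np.clip(-4.0 * s / c0, -5, 5))
    if rising:
        b0 = min(b0, -1e-3)
        b_lo, b_hi = -5.0, -1e-4
    else:
        b0 = max(b0, 1e-3)
        b_lo, b_hi = 1e-4, 5.0
    p0 = [-b0 * t_m, b0, c0, d0]
    bounds = ([-2000.0, b_lo, 1e-6, -1.0], [2000.0, b_hi, 2.0, 1.0])
    try:
        popt, _ = curve_fit(_logistic, day.astype(float), y, p0=p0,
                            bounds=bounds, jac=_logistic_jac, maxfev=20000)
    except RuntimeError as exc:
        raise LogisticFitError(f"{branch} logistic fit did not converge: {exc}",
                               branch=branch) from exc
    resid = y - _logistic(day, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    a, b, c, d = map(float, popt)
    if c < 0.01:
        raise LogisticFitError(f"{branch} fit degenerate (c={c:.4g})",
                               branch=branch, residual=rmse)
    return LogisticFit(branch, a, b, c, d,
                       window=(float(day[0]), float(day[-1])), rmse=rmse)


def fit_piecewise_logistic(series: DailySeries,
                           season: GrowingSeason | None = None
                           ) -> tuple[LogisticFit, LogisticFit]:
    """Fit the rising and descending limbs with separate logistics.

    The rising limb runs from SD to the peak day, the descending limb from
    the peak to ED (each needs at least 6 points).  Returns the two fits
    with their residual RMSE.
    """
    day, y = series.day, series.ndvi
    if season is None:
        season = GrowingSeason(int(day[0]), int(day[-1]))
    i_sd = int(np.searchsorted(day, season.sd))
    i_ed = int(np.searchsorted(day, season.ed))
    i_peak = i_sd + int(np.argmax(y[i_sd:i_ed + 1]))
    rising = _fit_branch(day[i_sd:i_peak + 1], y[i_sd:i_peak + 1], "rising")
    falling = _fit_branch(day[i_peak:i_ed + 1], y[i_peak:i_ed + 1], "descending")
    return rising, falling


def extract_inflection_dates(rising: LogisticFit, descending: LogisticFit,
                             window_slack: float = 3.0) -> tuple[float, float]:
    """Inflection dates (V6, R6) from the two fitted limbs.

    The logistic derivative is extremal at t = -a/b, so V6 and R6 are read
    directly off the fitted parameters.  An inflection falling outside its
    limb's fit window (with ``window_slack`` days of slack) indicates a
    failed fit and raises.
    """
    out = []
    for fit in (rising, descending):
        t = fit.midpoint
        lo, hi = fit.window
        if not (lo - window_slack <= t <= hi + window_slack):
            raise PhenologyExtractionError(
                f"{fit.branch} inflection {t:.1f} outside fit window "
                f"[{lo:.0f}, {hi:.0f}]")
        out.append(float(np.clip(t, lo, hi)))
    v6, r6 = out
    return v6, r6


def build_growth_phases(dates: PhenoDates, series: DailySeries) -> list[GrowthPhase]:
    """The four growth phases with boundary NDVI read from the series."""
    d = dates.as_dict()
    order = ["v1", "v6", "vt", "r4", "r6"]
    for a, b in zip(order, order[1:]):
        if d[a] >= d[b]:
            raise PhenologyExtractionError(
                f"zero-length phase: {a.upper()}={d[a]} not before {b.upper()}={d[b]}")
    phases = []
    for i, (a, b) in enumerate(zip(order, order[1:]), start=1):
        phases.append(GrowthPhase(f"GP{i}", d[a], d[b],
                                  series.value_at(d[a]), series.value_at(d[b])))
    return phases


def extract_phenology(series: DailySeries, season: GrowingSeason | None = None
                      ) -> tuple[PhenoDates, LogisticFit, LogisticFit]:
    """All five stage dates of one county-year series.

    Convenience wrapper: dynamic thresholds for V1/VT/R4, piecewise
    logistic inflections for V6/R6, rounded half-up to whole days.
    """
    if season is None:
        season = GrowingSeason(int(series.day[0]), int(series.day[-1]))
    v1, vt, r4 = extract_threshold_dates(series, season)
    rising, falling = fit_piecewise_logistic(series, season)
    v6f, r6f = extract_inflection_dates(rising, falling)
    dates = PhenoDates(v1=v1, v6=round_half_up(v6f), vt=vt, r4=r4,
                       r6=round_half_up(r6f))
    return dates, rising, falling
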