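"""Per-pixel NDVI preparation.

Turns 8-day composite NDVI into a smoothed, daily, phenologically adjusted
growing-season series, in four steps applied in order:

1. :func:`sg_smooth` — Savitzky-Golay smoothing on the 8-day grid;
2. :func:`interpolate_daily` — natural cubic spline to daily resolution;
3. :func:`detect_growing_season` — locate the valley minima (SD, ED)
   flanking the single seasonal peak;
4. :func:`phenologically_adjust` — truncate to [SD, ED] and re-index time
   as days since SD, so that series from pixels with different planting
   dates become comparable.

NDVI itself is computed from red and near-infrared surface reflectance by
:func:`compute_ndvi`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_filter

from .errors import (AmbiguousPeakError, InvalidInputError,
                     SeasonDetectionError)

__all__ = [
    "CompositeSeries",
    "DailySeries",
    "GrowingSeason",
    "compute_ndvi",
    "sg_smooth",
    "interpolate_daily",
    "detect_growing_season",
    "phenologically_adjust",
]


@dataclass(frozen=True)
class CompositeSeries:
    """One pixel-year of 8-day composite NDVI.

    ``doy`` holds the 1-based start day of each 8-day window and must be
    strictly increasing with spacing 8; a standard 365-day year therefore
    has 46 composites (windows starting on days 1, 9, ..., 361).
    """

    pixel_id: object
    year: int
    doy: np.ndarray
    ndvi: np.ndarray

    def __post_init__(self):
        doy = np.asarray(self.doy, dtype=float)
        ndvi = np.asarray(self.ndvi, dtype=float)
        if doy.ndim != 1 or doy.shape != ndvi.shape:
            raise InvalidInputError("doy and ndvi must be 1-D and equal length")
        if len(doy) >= 2 and not np.all(np.diff(doy) == 8):
            raise InvalidInputError("composite DOYs must increase with spacing 8")
        object.__setattr__(self, "doy", doy)
        object.__setattr__(self, "ndvi", ndvi)

    def __len__(self) -> int:
        return len(self.doy)


@dataclass(frozen=True)
class DailySeries:
    """Daily NDVI for one pixel (or county) and year.

    ``day`` is consecutive integers — calendar DOY before phenological
    adjustment, days-since-SD (starting at 0) after it.
    """

    series_id: object
    year: int
    day: np.ndarray
    ndvi: np.ndarray

    def __post_init__(self):
        day = np.asarray(self.day, dtype=int)
        ndvi = np.asarray(self.ndvi, dtype=float)
        if day.ndim != 1 or day.shape != ndvi.shape:
            raise InvalidInputError("day and ndvi must be 1-D and equal length")
        if len(day) >= 2 and not np.all(np.diff(day) == 1):
            raise InvalidInputError("daily series must have day spacing 1")
        object.__setattr__(self, "day", day)
        object.__setattr__(self, "ndvi", ndvi)

    def __len__(self) -> int:
        return len(self.day)

    def value_at(self, day: float) -> float:
        """NDVI at ``day``, linearly interpolated between grid days."""
        return float(np.interp(day, self.day, self.ndvi))


@dataclass(frozen=True)
class GrowingSeason:
    """Start (SD) and end (ED) day of the growing season.

    Both are days on the grid of the series they were detected in; SD < ED.
    """

    sd: int
    ed: int

    def __post_init__(self):
        if self.sd >= self.ed:
            raise InvalidInputError(f"season start {self.sd} must precede end {self.ed}")


def compute_ndvi(red, nir):
    """Normalized difference vegetation index (NIR − red)/(NIR + red).

    Parameters are surface reflectances in [0, 1]; scalars or arrays.
    Raises :class:`InvalidInputError` where red + nir == 0 (undefined).
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = red + nir
    if np.any(denom == 0):
        raise InvalidInputError("NDVI undefined where red + nir == 0")
    out = (nir - red) / denom
    return float(out) if out.ndim == 0 else out


def sg_smooth(series: CompositeSeries, window: int = 5, polyorder: int = 2) -> CompositeSeries:
    """Savitzky-Golay smoothing of a composite series on its own grid.

    Local least-squares polynomial of degree ``polyorder`` over ``window``
    composites; edges are handled by evaluating the edge-window polynomial
    fit (``mode='interp'``), so a series that already is a polynomial of
    degree <= polyorder passes through unchanged.
    """
    if window % 2 == 0:
        raise InvalidInputError("window must be odd")
    if not polyorder < window <= len(series):
        raise InvalidInputError(
            f"need polyorder < window <= series length, got "
            f"polyorder={polyorder}, window={window}, length={len(series)}")
    smoothed = savgol_filter(series.ndvi, window_length=window,
                             polyorder=polyorder, mode="interp")
    return replace(series, ndvi=smoothed)


def interpolate_daily(series: CompositeSeries) -> DailySeries:
    """Natural cubic spline through the composites, evaluated at every DOY.

    The spline passes exactly through the composite points; the daily grid
    covers [first composite DOY, last composite DOY].
    """
    if len(series) < 4:
        raise InvalidInputError("cubic spline interpolation needs >= 4 composites")
    spline = CubicSpline(series.doy, series.ndvi, bc_type="natural")
    day = np.arange(int(series.doy[0]), int(series.doy[-1]) + 1)
    return DailySeries(series.pixel_id, series.year, day, spline(day))


def _second_difference(y: np.ndarray) -> np.ndarray:
    """Discrete second derivative; endpoints padded with 0 (no curvature info)."""
    d2 = np.zeros_like(y)
    d2[1:-1] = y[2:] - 2.0 * y[1:-1] + y[:-2]
    return d2


def detect_growing_season(daily: DailySeries,
                          valley_frac: float = 0.01,
                          curvature_rel_tol: float = 0.1,
                          peak_prominence_frac: float = 0.1,
                          noise_mult: float = 8.0,
                          edge_method: str = "margin",
                          allow_multi_peak: bool = False) -> GrowingSeason:
    """Find the growing-season start (SD) and end (ED) around the NDVI peak.

    SD is the day where the curve begins to rise out of the valley bottom
    preceding the single seasonal peak; ED the mirror-image day after it.
    Operationally each is the day of the valley plateau nearest the peak:
    the last day before (first day after) the peak whose NDVI is still
    within ``valley_frac`` of the limb's amplitude of the valley minimum.
    At such a day the discrete second derivative is required to be small —
    below ``curvature_rel_tol`` times the limb's maximum curvature — and if
    it is not, the nearest day in the valley where it is small is used
    instead.

    Noise handling: the series is classed as quiet or noisy by the robust
    scale of its residual against a 15-day moving average — essentially
    zero for any smooth curve, positive whenever composite-scale noise
    survives smoothing and interpolation.  Quiet series use the exact rule
    above.  On noisy series the valley level is instead the median of the
    limb's low-value band (immune to noise dips) and the threshold margin
    is widened to ``noise_mult`` times a lag-8 second-difference noise
    scale, so that ringing and residual noise in the long flat valleys
    cannot pull the season edge onto a spurious dip.

    Raises :class:`SeasonDetectionError` for flat or monotone series and
    :class:`AmbiguousPeakError` when several peaks of comparable prominence
    exist, unless ``allow_multi_peak`` selects the highest one.
    """
    y = daily.ndvi
    w = 15
    pad = np.pad(y, w // 2, mode="reflect", reflect_type="odd")
    y_smooth = np.convolve(pad, np.ones(w) / w, mode="valid")
    resid = y - y_smooth
    sigma_fast = 1.4826 * float(np.median(np.abs(resid)))
    rng = float(np.max(y) - np.min(y))
    if rng <= 1e-9:
        raise SeasonDetectionError("series is flat; no seasonal peak")
    peaks, _ = find_peaks(y, prominence=peak_prominence_frac * rng)
    if len(peaks) == 0:
        raise SeasonDetectionError("no interior seasonal peak (monotone series?)")
    if len(peaks) > 1 and not allow_multi_peak:
        raise AmbiguousPeakError(
            f"{len(peaks)} peaks of comparable prominence at days "
            f"{daily.day[peaks].tolist()}; pass allow_multi_peak=True to take the highest")
    peak = int(peaks[np.argmax(y[peaks])])

    d2 = np.abs(_second_difference(y))

    def _edge(idx_limb: np.ndarray, nearest_last: bool) -> int:
        vals = y[idx_limb]
        vmin = float(np.min(vals))
        amp = float(y[peak] - vmin)
        if amp <= 1e-9:
            raise SeasonDetectionError("degenerate limb amplitude")
        if sigma_fast <= 0.2 * valley_frac * rng:
            # quiet series: exact valley-minimum semantics
            plateau = idx_limb[vals <= vmin + valley_frac * amp]
            cand = int(plateau[-1] if nearest_last else plateau[0])
            tol = curvature_rel_tol * float(np.max(d2[idx_limb]))
            if d2[cand] > tol:
                ok = plateau[d2[plateau] <= tol]
                if len(ok):
                    cand = int(ok[np.argmin(np.abs(ok - cand))])
            return cand
        # noisy series: model-based edge.  The valley-fraction crossing
        # itself sits in a low-slope, noise-dominated region, so locate the
        # steep 20% and 80% amplitude crossings instead (small jitter),
        # infer the limb's logistic steepness from their separation, and
        # extrapolate down to the valley_frac elevation.  This keeps the
        # edge definition (curve exceeds the valley by valley_frac of the
        # amplitude) while making it robust and steepness-adaptive.
        vs = y_smooth[idx_limb]
        q10 = float(np.percentile(vs, 10))
        band = idx_limb[vs <= q10 + 0.15 * amp]
        base_level = float(np.median(y_smooth[band]))
        amp_s = float(y_smooth[peak]) - base_level
        if amp_s <= 1e-6:
            raise SeasonDetectionError("degenerate limb amplitude")

        def _crossing(level):
            """Fractional day of the crossing adjacent to the peak."""
            rel = vs - level
            if nearest_last:
                below = np.nonzero(rel < 0)[0]
                if len(below) == 0 or below[-1] == len(vs) - 1:
                    return None
                i = below[-1]
                j = i + 1
            else:
                below = np.nonzero(rel < 0)[0]
                if len(below) == 0 or below[0] == 0:
                    return None
                i = below[0]
                j = i - 1
            f = rel[i] / (rel[i] - rel[j])
            return float(idx_limb[i] + f * (idx_limb[j] - idx_limb[i]))

        t20 = _crossing(base_level + 0.2 * amp_s)
        t80 = _crossing(base_level + 0.8 * amp_s)
        if edge_method == "model" and t20 is not None and t80 is not None \
                and abs(t80 - t20) > 1.0:
            k_hat = (np.log(4.0) + np.log(4.0)) / abs(t80 - t20)
            f = max(valley_frac, 1e-4)
            reach = (np.log((1.0 - f) / f) - np.log(4.0)) / k_hat
            cand = t20 - reach if nearest_last else t20 + reach
            cand = int(round(np.clip(cand, idx_limb[0], idx_limb[-1])))
            return cand
        # fallback: margin crossing with a lag-8 noise scale
        inner = band[(band - idx_limb[0] >= 8) & (idx_limb[-1] - band >= 8)]
        sigma = sigma_fast
        if len(inner):
            lag2 = np.abs(y[inner + 8] - 2.0 * y[inner] + y[inner - 8])
            sigma = max(sigma, 1.4826 * float(np.median(lag2)) / np.sqrt(6.0))
        margin = max(valley_frac * amp, noise_mult * sigma)
        level = min(base_level + margin, float(np.min(vs)) + 0.5 * amp)
        below = idx_limb[vs <= level]
        return int(below[-1] if nearest_last else below[0])

    sd_idx = _edge(np.arange(0, peak + 1), nearest_last=True)
    ed_idx = _edge(np.arange(peak, len(y)), nearest_last=False)
    if sd_idx >= ed_idx:
        raise SeasonDetectionError("detected season collapsed to zero length")
    return GrowingSeason(sd=int(daily.day[sd_idx]), ed=int(daily.day[ed_idx]))


def phenologically_adjust(daily: DailySeries, season: GrowingSeason) -> DailySeries:
    """Truncate to [SD, ED] and re-index time as days since SD.

    Days before SD and after ED are excluded; index 0 of the result maps to
    the calendar day ``season.sd``. Applying the function again with the
    season expressed in the adjusted coordinates is a no-op.
    """
    if season.sd < daily.day[0] or season.ed > daily.day[-1]:
        raise InvalidInputError("season must lie inside the daily series")
    keep = (daily.day >= season.sd) & (daily.day <= season.ed)
    return DailySeries(daily.series_id, daily.year,
                       daily.day[keep] - season.sd, daily.ndvi[keep])
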