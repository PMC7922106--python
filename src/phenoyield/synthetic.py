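"""Synthetic corn-NDVI landscapes with known phenological ground truth.

The generator emulates the data a county-level corn yield study consumes:

* per-pixel seasonal NDVI that follows a double-logistic curve
  ``base + amplitude * (logistic(rise) - logistic(fall))`` with spatially
  varying planting dates and green-up / senescence rates;
* daily samples degraded by additive noise and cloud-like negative dropout,
  then reduced to 8-day maximum-value composites (MVC) — the compositing
  step suppresses the negatively biased cloud contamination;
* mixed 250-m pixels carrying a corn area fraction per pixel;
* county-year yields generated as a linear function of the true
  phenological metrics plus Gaussian noise.

Because every curve parameter is known, the true stage dates (emergence
V1, jointing V6, tasseling VT, dough R4, maturity R6) and the true
duration/rate metrics of the four growth phases are available analytically,
so every downstream stage can be tested by recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .errors import InvalidInputError
from .prep import CompositeSeries, DailySeries

__all__ = [
    "DoubleLogisticParams",
    "CurvePriors",
    "SimConfig",
    "GroundTruth",
    "Panel",
    "double_logistic",
    "simulate_pixel_curve",
    "simulate_composites",
    "simulate_yields",
    "simulate_panel",
    "analytic_stage_dates",
    "metrics_from_dates",
    "METRIC_NAMES",
]

#: the eight phenological metrics, in canonical order
METRIC_NAMES = ("gp1d", "gp1r", "gp2d", "gp2r", "gp3d", "gp3r", "gp4d", "gp4r")

#: generating coefficients used by default for synthetic yields
#: (kg ha^-1 per metric unit): positive on GP2 duration and rate and on GP3
#: duration, negative on GP4 rate — the sign structure a well-behaved corn
#: season exhibits (longer/faster vegetative growth and a longer peak phase
#: raise yield; faster senescence lowers it).
DEFAULT_YIELD_BETAS = {
    "intercept": -10084.25,
    "gp2d": 360.58,
    "gp2r": 953476.78,
    "gp3d": 97.00,
    "gp4r": -102453.38,
}


@dataclass(frozen=True)
class DoubleLogisticParams:
    """Parameters of one pixel-year seasonal curve.

    ``ndvi(t) = base + amplitude * (expit(rise_rate*(t - rise_midpoint))
    - expit(fall_rate*(t - fall_midpoint)))``.  The rising inflection is at
    ``rise_midpoint`` (the true jointing date V6) and the falling one at
    ``fall_midpoint`` (the true maturity date R6).
    """

    base: float
    amplitude: float
    rise_midpoint: float
    rise_rate: float
    fall_midpoint: float
    fall_rate: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidInputError("amplitude must be >= 0")
        if self.rise_midpoint >= self.fall_midpoint:
            raise InvalidInputError(
                f"rise midpoint {self.rise_midpoint} must precede fall "
                f"midpoint {self.fall_midpoint}")
        if self.rise_rate <= 0 or self.fall_rate <= 0:
            raise InvalidInputError("steepness parameters must be positive")
        if not (-1.0 <= self.base and self.base + self.amplitude <= 1.0):
            raise InvalidInputError("curve must stay within the NDVI range [-1, 1]")


def double_logistic(t, p: DoubleLogisticParams):
    """Evaluate the seasonal curve at (array of) day ``t``."""
    t = np.asarray(t, dtype=float)
    rise = expit(p.rise_rate * (t - p.rise_midpoint))
    fall = expit(p.fall_rate * (t - p.fall_midpoint))
    return p.base + p.amplitude * (rise - fall)


def simulate_pixel_curve(params: DoubleLogisticParams, day_grid) -> np.ndarray:
    """Noise-free daily NDVI for one pixel-year.

    ``day_grid`` must cover at least [rise_midpoint - 60, fall_midpoint + 60]
    so that both valley bottoms are represented.
    """
    day_grid = np.asarray(day_grid, dtype=float)
    if day_grid[0] > params.rise_midpoint - 60 or day_grid[-1] < params.fall_midpoint + 60:
        raise InvalidInputError(
            "day grid must cover [rise_midpoint - 60, fall_midpoint + 60]")
    return double_logistic(day_grid, params)


def mvc_window_starts(first_day: int, last_day: int) -> np.ndarray:
    """Start days of the 8-day compositing windows covering [first, last].

    A standard 365-day year starting on day 1 gives 46 windows
    (1, 9, ..., 361; the last one truncated at day 365).
    """
    return np.arange(first_day, last_day + 1, 8)


def simulate_composites(daily: DailySeries, noise_sd: float, dropout_prob: float,
                        seed, dropout_bias: float = 0.3) -> CompositeSeries:
    """8-day maximum-value compositing of a noise- and cloud-degraded series.

    Each daily sample receives additive N(0, noise_sd) noise; with
    probability ``dropout_prob`` it is additionally depressed by
    ``dropout_bias`` NDVI units, mimicking cloud contamination.  The
    composite value for each window is the maximum of the degraded samples
    in it — which is why MVC suppresses the (negatively biased) cloud hits.
    Composites are timestamped with the window start day.
    """
    if not 0.0 <= dropout_prob < 1.0:
        raise InvalidInputError("dropout_prob must be in [0, 1)")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    y = daily.ndvi.astype(float).copy()
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=y.shape)
    if dropout_prob > 0:
        y -= dropout_bias * (rng.random(y.shape) < dropout_prob)
    starts = mvc_window_starts(int(daily.day[0]), int(daily.day[-1]))
    idx = (daily.day - daily.day[0]) // 8
    comp = np.full(len(starts), -np.inf)
    np.maximum.at(comp, idx, y)
    return CompositeSeries(daily.series_id, daily.year, starts, comp)


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _crossing(day_a: float, day_b: float, fn, level: float) -> float:
    """Day in [day_a, day_b] where fn crosses `level` (fn monotone enough)."""
    return float(brentq(lambda t: fn(t) - level, day_a, day_b, xtol=1e-6))


def analytic_stage_dates(curve_fn, t0: float, t1: float,
                         onset_frac: float = 0.01) -> dict:
    """True SD/ED and stage dates of a smooth single-peaked curve.

    ``curve_fn`` is a callable day -> NDVI on [t0, t1].  SD (ED) is the
    first (last) day the curve exceeds the valley value by ``onset_frac``
    of the limb amplitude; V1/VT are the 10%/90% upward crossings of the
    SD-to-maximum range on the rising limb, R4 the 10% downward crossing
    toward the ED value on the falling limb, and V6/R6 the inflections
    (extrema of the first derivative) of each limb.  All dates are
    fractional days.
    """
    res = minimize_scalar(lambda t: -curve_fn(t), bounds=(t0, t1), method="bounded",
                          options={"xatol": 1e-6})
    t_peak = float(res.x)
    y_peak = float(curve_fn(t_peak))
    y_left = float(curve_fn(t0))
    y_right = float(curve_fn(t1))

    sd = _crossing(t0, t_peak, curve_fn, y_left + onset_frac * (y_peak - y_left))
    ed = _crossing(t_peak, t1, curve_fn, y_right + onset_frac * (y_peak - y_right))
    y_sd, y_ed = float(curve_fn(sd)), float(curve_fn(ed))

    v1 = _crossing(sd, t_peak, curve_fn, y_sd + 0.10 * (y_peak - y_sd))
    vt = _crossing(sd, t_peak, curve_fn, y_sd + 0.90 * (y_peak - y_sd))
    r4 = _crossing(t_peak, ed, curve_fn, y_peak - 0.10 * (y_peak - y_ed))

    def slope(t):
        h = 1e-4
        return (curve_fn(t + h) - curve_fn(t - h)) / (2 * h)

    v6 = float(minimize_scalar(lambda t: -slope(t), bounds=(sd, t_peak),
                               method="bounded", options={"xatol": 1e-6}).x)
    r6 = float(minimize_scalar(slope, bounds=(t_peak, ed),
                               method="bounded", options={"xatol": 1e-6}).x)
    return {"sd": sd, "v1": v1, "v6": v6, "vt": vt, "r4": r4, "r6": r6, "ed": ed,
            "peak": t_peak}


def metrics_from_dates(dates: dict, curve_fn) -> dict:
    """Duration (days) and rate (ΔNDVI/day) of the four growth phases."""
    bounds = [("gp1", dates["v1"], dates["v6"]), ("gp2", dates["v6"], dates["vt"]),
              ("gp3", dates["vt"], dates["r4"]), ("gp4", dates["r4"], dates["r6"])]
    out = {}
    for label, a, b in bounds:
        dur = b - a
        out[label + "d"] = dur
        out[label + "r"] = (float(curve_fn(b)) - float(curve_fn(a))) / dur
    return out


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurvePriors:
    """Hierarchical priors for the double-logistic parameters.

    Each entry is (mean, sd).  County means are drawn once per county;
    year effects (shared weather shocks) once per year; county-year and
    pixel-level jitter on top.  Units: NDVI for base/amplitude, calendar
    DOY for midpoints, day^-1 for rates.
    """

    base: tuple = (0.18, 0.015)
    amplitude: tuple = (0.55, 0.04)
    rise_midpoint: tuple = (150.0, 7.0)
    season_gap: tuple = (95.0, 5.0)          # fall minus rise midpoint
    rise_rate: tuple = (0.14, 0.02)
    fall_rate: tuple = (0.11, 0.015)
    year_sd: dict = field(default_factory=lambda: {
        "rise_midpoint": 4.0, "season_gap": 4.0, "amplitude": 0.02,
        "rise_rate": 0.010, "fall_rate": 0.008})
    county_year_sd: dict = field(default_factory=lambda: {
        "rise_midpoint": 2.5, "season_gap": 3.0, "amplitude": 0.015,
        "rise_rate": 0.008, "fall_rate": 0.006})
    pixel_sd: dict = field(default_factory=lambda: {
        "rise_midpoint": 1.5, "season_gap": 1.5, "amplitude": 0.01,
        "base": 0.005, "rise_rate": 0.004, "fall_rate": 0.003})


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic panel.

    Defaults describe a desk-scale corn belt: 30 counties x 10 years
    (300 county-years), 8 mixed pixels per county with corn fractions in
    [0.4, 0.95], composite noise of 0.02 NDVI, 5% cloud dropout with a
    -0.3 NDVI bias, and yields generated from four true metrics with noise
    calibrated to a generating R^2 of 0.65.
    """

    n_counties: int = 30
    pixels_per_county: int = 8
    years: tuple = tuple(range(2009, 2019))
    corn_fraction_range: tuple = (0.4, 0.95)
    curve_priors: CurvePriors = field(default_factory=CurvePriors)
    noise_sd: float = 0.02
    dropout_prob: float = 0.05
    dropout_bias: float = 0.3
    purity_threshold: float = 0.70
    yield_betas: dict = field(default_factory=lambda: dict(DEFAULT_YIELD_BETAS))
    yield_noise_sd: float | None = None     # None -> calibrated to target R^2
    yield_target_r2: float = 0.65
    semi_arid_fraction: float = 1 / 3       # first counties form the semi-arid group
    seed: int = 0

    def __post_init__(self):
        if self.n_counties <= 0 or self.pixels_per_county <= 0:
            raise InvalidInputError("need at least one county and one pixel")
        if len(self.years) == 0:
            raise InvalidInputError("need at least one year")
        lo, hi = self.corn_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidInputError("corn_fraction_range must be within [0, 1]")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise InvalidInputError("dropout_prob must be in [0, 1)")
        bad = set(self.yield_betas) - set(METRIC_NAMES) - {"intercept"}
        if bad:
            raise InvalidInputError(f"unknown yield beta keys: {sorted(bad)}")
        if not all(np.isfinite(v) for v in self.yield_betas.values()):
            raise InvalidInputError("yield betas must be finite")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``pixel_params`` — one row per pixel-year with the curve parameters and
    the analytic stage dates; ``county_truth`` — one row per county-year
    with the corn-fraction-weighted true dates and the eight true metrics;
    ``generating`` — the yield-generating betas, the calibrated noise sd
    and the generating R^2 (signal variance over total variance).
    """

    pixel_params: pd.DataFrame
    county_truth: pd.DataFrame
    generating: dict

    def pixel_dates(self) -> pd.DataFrame:
        """Analytic stage dates for every pixel-year (computed on demand).

        True V6/R6 equal the curve's rise/fall midpoints; the remaining
        dates are the exact threshold crossings of the noise-free curve.
        """
        rows = []
        for r in self.pixel_params.itertuples():
            p = DoubleLogisticParams(r.base, r.amplitude, r.rise_midpoint,
                                     r.rise_rate, r.fall_midpoint, r.fall_rate)
            t0 = p.rise_midpoint - 90.0
            t1 = p.fall_midpoint + 90.0
            dates = analytic_stage_dates(lambda t: double_logistic(t, p), t0, t1)
            rows.append({"county_id": r.county_id, "pixel_id": r.pixel_id,
                         "year": r.year,
                         **{"true_" + k: v for k, v in dates.items()}})
        return pd.DataFrame(rows)


@dataclass
class Panel:
    """One simulated study: composites, corn fractions, yields, truth."""

    composites: pd.DataFrame      # county_id, pixel_id, year, doy, ndvi
    fractions: pd.DataFrame       # county_id, pixel_id, corn_fraction
    yields: pd.DataFrame          # county_id, year, region_group, yield_kg_ha
    truth: GroundTruth
    config: SimConfig

    def write_csvs(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.composites.to_csv(out / "composites.csv", index=False)
        self.fractions.to_csv(out / "fractions.csv", index=False)
        cols = ["county_id", "year", "region_group", "yield_kg_ha"]
        self.yields[cols].to_csv(out / "yields.csv", index=False)
        self.truth.pixel_params.to_csv(out / "truth_pixels.csv", index=False)
        self.truth.county_truth.to_csv(out / "truth_counties.csv", index=False)


def _norm(rng, mean_sd):
    return rng.normal(mean_sd[0], mean_sd[1])


def _draw_pixel_params(cfg: SimConfig) -> pd.DataFrame:
    """Hierarchical parameter draws: county means + year shocks + jitter."""
    pri = cfg.curve_priors
    county_rng = np.random.default_rng([cfg.seed, 101])
    county_means = {
        c: {"base": _norm(county_rng, pri.base),
            "amplitude": _norm(county_rng, pri.amplitude),
            "rise_midpoint": _norm(county_rng, pri.rise_midpoint),
            "season_gap": _norm(county_rng, pri.season_gap),
            "rise_rate": _norm(county_rng, pri.rise_rate),
            "fall_rate": _norm(county_rng, pri.fall_rate)}
        for c in range(cfg.n_counties)}
    year_rng = np.random.default_rng([cfg.seed, 202])
    year_fx = {y: {k: year_rng.normal(0.0, s) for k, s in pri.year_sd.items()}
               for y in cfg.years}
    cy_rng = np.random.default_rng([cfg.seed, 303])
    rows = []
    for c in range(cfg.n_counties):
        for y in cfg.years:
            cy = {k: cy_rng.normal(0.0, s) for k, s in pri.county_year_sd.items()}
            for p in range(cfg.pixels_per_county):
                # one stream per pixel-year so panels extend without redraws
                prng = np.random.default_rng([cfg.seed, c, p, y])
                px = {k: prng.normal(0.0, s) for k, s in pri.pixel_sd.items()}
                m = county_means[c]
                base = np.clip(m["base"] + px.get("base", 0.0), 0.08, 0.30)
                amp = np.clip(m["amplitude"] + year_fx[y]["amplitude"]
                              + cy["amplitude"] + px["amplitude"], 0.30, 0.78)
                m1 = np.clip(m["rise_midpoint"] + year_fx[y]["rise_midpoint"]
                             + cy["rise_midpoint"] + px["rise_midpoint"], 120.0, 185.0)
                gap = m["season_gap"] + year_fx[y]["season_gap"] + cy["season_gap"] \
                    + px["season_gap"]
                m2 = np.clip(m1 + np.clip(gap, 65.0, 125.0), None, 300.0)
                k1 = np.clip(m["rise_rate"] + year_fx[y]["rise_rate"]
                             + cy["rise_rate"] + px["rise_rate"], 0.085, 0.25)
                k2 = np.clip(m["fall_rate"] + year_fx[y]["fall_rate"]
                             + cy["fall_rate"] + px["fall_rate"], 0.08, 0.20)
                rows.append({"county_id": c, "pixel_id": p, "year": y,
                             "base": base, "amplitude": amp,
                             "rise_midpoint": m1, "rise_rate": k1,
                             "fall_midpoint": m2, "fall_rate": k2})
    return pd.DataFrame(rows)


def _county_truth_rows(params: pd.DataFrame, fractions: pd.DataFrame,
                       purity_threshold: float, day_grid: np.ndarray) -> pd.DataFrame:
    """True dates/metrics of the fraction-weighted mean curve of pure pixels."""
    fr = fractions.set_index(["county_id", "pixel_id"])["corn_fraction"]
    rows = []
    for (c, y), grp in params.groupby(["county_id", "year"]):
        w = fr.loc[list(zip(grp["county_id"], grp["pixel_id"]))].to_numpy()
        pure = w > purity_threshold
        if not pure.any():
            continue
        plist = [DoubleLogisticParams(r.base, r.amplitude, r.rise_midpoint,
                                      r.rise_rate, r.fall_midpoint, r.fall_rate)
                 for r in grp[pure].itertuples()]
        wsel = w[pure] / w[pure].sum()

        def county_curve(t, _p=plist, _w=wsel):
            return sum(wi * double_logistic(t, pi) for wi, pi in zip(_w, _p))

        dates = analytic_stage_dates(county_curve, day_grid[0], day_grid[-1])
        mets = metrics_from_dates(dates, county_curve)
        rows.append({"county_id": c, "year": y,
                     **{"true_" + k: v for k, v in dates.items()},
                     **{"true_" + k: v for k, v in mets.items()}})
    return pd.DataFrame(rows)


def simulate_yields(truth: GroundTruth, betas: dict, noise_sd: float | None,
                    seed, target_r2: float | None = None,
                    region_group: pd.Series | None = None) -> pd.DataFrame:
    """County-year yields linear in the true metrics plus Gaussian noise.

    ``yield = intercept + sum_k beta_k * true_metric_k + N(0, noise_sd)``.
    With ``noise_sd=None`` the noise is calibrated from the simulated
    variance decomposition so that the generating R^2
    (signal variance / total variance) equals ``target_r2``.  The realized
    generating quantities are stored in ``truth.generating``.
    """
    if not all(np.isfinite(v) for v in betas.values()):
        raise InvalidInputError("yield betas must be finite")
    ct = truth.county_truth
    signal = np.full(len(ct), float(betas.get("intercept", 0.0)))
    for name, b in betas.items():
        if name == "intercept":
            continue
        if name not in METRIC_NAMES:
            raise InvalidInputError(f"beta on unknown metric {name!r}")
        signal = signal + b * ct["true_" + name].to_numpy()
    var_signal = float(np.var(signal, ddof=1))
    if noise_sd is None:
        if not (target_r2 and 0 < target_r2 < 1):
            raise InvalidInputError("target_r2 in (0,1) required to calibrate noise")
        noise_sd = float(np.sqrt(var_signal * (1.0 / target_r2 - 1.0)))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(ct))
    # generating R^2 from the realized variance decomposition of this panel:
    # the share of yield variance the true signal explains in these draws
    generating_r2 = var_signal / (var_signal + float(np.var(noise, ddof=1)))
    truth.generating = {"betas": dict(betas), "noise_sd": float(noise_sd),
                        "signal_var": var_signal,
                        "target_r2": None if target_r2 is None else float(target_r2),
                        "generating_r2": float(generating_r2)}
    out = ct[["county_id", "year"]].copy()
    if region_group is not None:
        out["region_group"] = out["county_id"].map(region_group)
    out["yield_kg_ha"] = signal + noise
    out["yield_signal"] = signal
    return out


def simulate_panel(config: SimConfig) -> Panel:
    """Simulate one full study panel, reproducibly from ``config.seed``."""
    day_grid = np.arange(1, 366)
    params = _draw_pixel_params(config)

    frac_rng = np.random.default_rng([config.seed, 404])
    lo, hi = config.corn_fraction_range
    fr_rows = [{"county_id": c, "pixel_id": p,
                "corn_fraction": frac_rng.uniform(lo, hi)}
               for c in range(config.n_counties)
               for p in range(config.pixels_per_county)]
    fractions = pd.DataFrame(fr_rows)

    cols = {k: [] for k in ("county_id", "pixel_id", "year", "doy", "ndvi")}
    for r in params.itertuples():
        p = DoubleLogisticParams(r.base, r.amplitude, r.rise_midpoint,
                                 r.rise_rate, r.fall_midpoint, r.fall_rate)
        daily = DailySeries((r.county_id, r.pixel_id), r.year, day_grid,
                            simulate_pixel_curve(p, day_grid))
        comp = simulate_composites(
            daily, config.noise_sd, config.dropout_prob,
            seed=[config.seed, 505, r.county_id, r.pixel_id, r.year],
            dropout_bias=config.dropout_bias)
        n = len(comp.doy)
        cols["county_id"].append(np.full(n, r.county_id))
        cols["pixel_id"].append(np.full(n, r.pixel_id))
        cols["year"].append(np.full(n, r.year))
        cols["doy"].append(comp.doy.astype(int))
        cols["ndvi"].append(comp.ndvi)
    composites = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})

    county_truth = _county_truth_rows(params, fractions,
                                      config.purity_threshold, day_grid)
    n_dropped = config.n_counties * len(config.years) - len(county_truth)
    if n_dropped:
        warnings.warn(f"{n_dropped} county-years have no pixel above the "
                      f"purity threshold and carry no truth/yield")

    n_semi = max(1, int(round(config.semi_arid_fraction * config.n_counties)))
    region = pd.Series({c: ("semi_arid" if c < n_semi else "non_semi_arid")
                        for c in range(config.n_counties)})

    truth = GroundTruth(pixel_params=params, county_truth=county_truth,
                        generating={})
    yields = simulate_yields(truth, config.yield_betas, config.yield_noise_sd,
                             seed=[config.seed, 606],
                             target_r2=config.yield_target_r2,
                             region_group=region)
    return Panel(composites=composites, fractions=fractions, yields=yields,
                 truth=truth, config=config)
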