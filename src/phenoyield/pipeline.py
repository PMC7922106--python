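"""End-to-end orchestration: composites -> metrics -> yield models.

``run_pipeline`` executes the four processing steps in order —

1. per-pixel preparation (smooth, interpolate, season detection,
   phenological adjustment),
2. county aggregation of corn-dominated pixels,
3. stage-date and metric extraction per county-year,
4. stepwise yield regression and leave-one-year-out cross-validation per
   region group —

and returns every stage table together with a :class:`RunManifest` that
accounts for each input row (carried downstream, or dropped with a
reason).  Inputs are either a :class:`~phenoyield.synthetic.SimConfig`
(the panel is simulated), a :class:`~phenoyield.synthetic.Panel`, or a
directory of the long-format CSVs the generator writes.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregation, metrics as metrics_mod, modeling
from .errors import InvalidInputError, PhenoYieldError
from .phenology import extract_phenology
from .prep import (CompositeSeries, DailySeries, detect_growing_season,
                   interpolate_daily, phenologically_adjust, sg_smooth)
from .synthetic import METRIC_NAMES, Panel, SimConfig, simulate_panel

log = logging.getLogger(__name__)

__all__ = ["PipelineParams", "RunManifest", "PipelineResult",
           "run_pipeline", "format_report"]

REGION_GROUPS = ("whole", "semi_arid", "non_semi_arid")


@dataclass(frozen=True)
class PipelineParams:
    """Analysis parameters shared by all stages (units in docs/methods.md)."""

    sg_window: int = 5               # composites; Savitzky-Golay window
    sg_polyorder: int = 2
    purity_threshold: float = 0.70   # corn fraction, strict inequality
    valley_frac: float = 0.01        # season-edge plateau, fraction of amplitude
    curvature_rel_tol: float = 0.1   # of the limb's max |second difference|
    allow_multi_peak: bool = False
    season_consensus_days: int = 3   # pixel SD/ED pulled this close to the
                                     # county-year median before trimming
    edge_method: str = "margin"      # season-edge rule on noisy series
                                     # ("margin" level-crossing or "model"
                                     # logistic-extrapolated onset)
    maxr2_stride: int = 1            # 1 = daily scan, 8 = composite step
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_cap: float = 4.0
    cv_r2_method: str = "corr"


@dataclass
class RunManifest:
    """Provenance record: what went in, what came out, what was dropped."""

    config_hash: str
    seed: int | None
    timings: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)

    def drop(self, stage: str, reason: str, **ids):
        self.dropped.append({"stage": stage, "reason": reason, **ids})
        log.warning("%s: dropped %s (%s)", stage, ids, reason)


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    county_series: pd.DataFrame      # county_id, year, adj_day, ndvi
    county_sd: pd.DataFrame          # county_id, year, sd_cal (weighted mean)
    dates: pd.DataFrame              # per county-year stage dates
    metrics_tables: dict             # region group -> MetricsRow table
    maxr2: dict                      # region group -> MaxR2Selection
    univariate: dict                 # region group -> DataFrame (Table-1 style)
    models: dict                     # (group, 'pheno'|'pheno_maxr2') -> RegressionModel
    cv: dict                         # group -> CVResult
    manifest: RunManifest


def _config_hash(*objs) -> str:
    h = hashlib.sha256()
    for o in objs:
        h.update(repr(o).encode())
    return h.hexdigest()[:16]


def _prep_stage(composites: pd.DataFrame, params: PipelineParams,
                manifest: RunManifest) -> dict:
    """Per-pixel smoothing, daily interpolation, season detection, adjustment.

    When all pixel-years share one complete 8-day grid, smoothing and
    spline interpolation run batched over the whole panel (numerically
    identical to the per-series functions); otherwise each series is
    processed individually.
    """
    from scipy.interpolate import CubicSpline
    from scipy.signal import savgol_filter

    wide = composites.pivot_table(index=["county_id", "pixel_id", "year"],
                                  columns="doy", values="ndvi")
    doy = wide.columns.to_numpy(dtype=float)
    prepped = {}
    if not wide.isna().any().any() and np.all(np.diff(doy) == 8):
        smooth = savgol_filter(wide.to_numpy(), params.sg_window,
                               params.sg_polyorder, axis=1, mode="interp")
        days = np.arange(int(doy[0]), int(doy[-1]) + 1)
        dailies = CubicSpline(doy, smooth.T, bc_type="natural")(days).T
        for (c, p, y), vals in zip(wide.index, dailies):
            daily = DailySeries((c, p), y, days, vals)
            try:
                season = detect_growing_season(
                    daily, valley_frac=params.valley_frac,
                    curvature_rel_tol=params.curvature_rel_tol,
                    edge_method=params.edge_method,
                    allow_multi_peak=params.allow_multi_peak)
                prepped[(c, p, y)] = (daily, season)
            except PhenoYieldError as exc:
                manifest.drop("prep", str(exc), county_id=c, pixel_id=p, year=y)
        return prepped
    for (c, p, y), grp in composites.groupby(["county_id", "pixel_id", "year"]):
        grp = grp.sort_values("doy")
        try:
            comp = CompositeSeries((c, p), y, grp["doy"].to_numpy(),
                                   grp["ndvi"].to_numpy())
            smooth = sg_smooth(comp, params.sg_window, params.sg_polyorder)
            daily = interpolate_daily(smooth)
            season = detect_growing_season(
                daily, valley_frac=params.valley_frac,
                curvature_rel_tol=params.curvature_rel_tol,
                edge_method=params.edge_method,
                allow_multi_peak=params.allow_multi_peak)
            prepped[(c, p, y)] = (daily, season)
        except PhenoYieldError as exc:
            manifest.drop("prep", str(exc), county_id=c, pixel_id=p, year=y)
    return prepped


def _aggregate_stage(prepped: dict, fractions: pd.DataFrame,
                     params: PipelineParams, manifest: RunManifest
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select corn-dominated pixels, refine their seasons, aggregate.

    Single-pixel season detection on noisy series jitters by several days;
    within one county-year the true season spread is much smaller.  Before
    trimming, each pixel's detected SD/ED is therefore pulled to within
    ``params.season_consensus_days`` of the county-year median (pixels keep
    genuine small offsets, outlier detections are corrected), which keeps
    the adjusted axes of the contributing pixels aligned.
    """
    from .prep import GrowingSeason

    frac = fractions.set_index(["county_id", "pixel_id"])["corn_fraction"]
    county_years = sorted({(c, y) for (c, p, y) in prepped})
    tol = params.season_consensus_days
    series_rows, sd_rows = [], []
    for c, y in county_years:
        pixels = [(p, s, season) for (cc, p, yy), (s, season) in prepped.items()
                  if cc == c and yy == y]
        sel = [(p, s, season) for p, s, season in pixels
               if frac.get((c, p), 0.0) > params.purity_threshold]
        if not sel:
            manifest.drop("aggregate", "no corn-dominated pixel",
                          county_id=c, year=y)
            continue
        med_sd = float(np.median([season.sd for _, _, season in sel]))
        med_ed = float(np.median([season.ed for _, _, season in sel]))
        trimmed = []
        for p, daily, season in sel:
            sd = int(round(med_sd + np.clip(season.sd - med_sd, -tol, tol)))
            ed = int(round(med_ed + np.clip(season.ed - med_ed, -tol, tol)))
            sd = max(sd, int(daily.day[0]))
            ed = min(ed, int(daily.day[-1]))
            trimmed.append((p, phenologically_adjust(
                daily, GrowingSeason(sd, ed)), GrowingSeason(sd, ed)))
        sel = trimmed
        weights = [float(frac[(c, p)]) for p, _, _ in sel]
        county = aggregation.county_weighted_ndvi(
            [s for _, s, _ in sel], weights, county_id=c)
        sd_cal = float(np.average([season.sd for _, _, season in sel],
                                  weights=weights))
        series_rows.append(pd.DataFrame({
            "county_id": c, "year": y, "adj_day": county.day,
            "ndvi": county.ndvi}))
        sd_rows.append({"county_id": c, "year": y, "sd_cal": sd_cal,
                        "n_pixels": len(sel)})
    if not series_rows:
        raise InvalidInputError("no county-year survived aggregation")
    return (pd.concat(series_rows, ignore_index=True), pd.DataFrame(sd_rows))


def _phenology_stage(county_series: pd.DataFrame, county_sd: pd.DataFrame,
                     manifest: RunManifest) -> tuple[pd.DataFrame, dict]:
    sd_map = county_sd.set_index(["county_id", "year"])["sd_cal"]
    rows, phases_map = [], {}
    from .phenology import build_growth_phases
    for (c, y), grp in county_series.groupby(["county_id", "year"]):
        grp = grp.sort_values("adj_day")
        series = DailySeries(c, y, grp["adj_day"].to_numpy(),
                             grp["ndvi"].to_numpy())
        try:
            dates, rising, falling = extract_phenology(series)
            phases = build_growth_phases(dates, series)
        except PhenoYieldError as exc:
            manifest.drop("phenology", str(exc), county_id=c, year=y)
            continue
        phases_map[(c, y)] = phases
        rows.append({"county_id": c, "year": y, "sd_cal": float(sd_map[(c, y)]),
                     **dates.as_dict(),
                     "fit_rmse_rise": rising.rmse, "fit_rmse_fall": falling.rmse})
    if not rows:
        raise InvalidInputError("no county-year survived phenology extraction")
    return pd.DataFrame(rows), phases_map


def _metrics_stage(phases_map: dict, county_series: pd.DataFrame,
                   yields: pd.DataFrame, params: PipelineParams
                   ) -> tuple[dict, dict]:
    met_rows = []
    for (c, y), phases in phases_map.items():
        met_rows.append({"county_id": c, "year": y,
                         **metrics_mod.metrics_from_phases(phases)})
    base = pd.DataFrame(met_rows).merge(
        yields[["county_id", "year", "region_group", "yield_kg_ha"]],
        on=["county_id", "year"], how="left")
    tables, selections = {}, {}
    for group in REGION_GROUPS:
        rows = base if group == "whole" else base[base["region_group"] == group]
        series = county_series.merge(rows[["county_id", "year"]],
                                     on=["county_id", "year"])
        sel = metrics_mod.select_max_r2(series, rows.dropna(subset=["yield_kg_ha"]),
                                        stride=params.maxr2_stride)
        tables[group] = rows.merge(sel.values, on=["county_id", "year"],
                                   how="left")
        selections[group] = sel
    return tables, selections


def _modeling_stage(tables: dict, params: PipelineParams
                    ) -> tuple[dict, dict, dict]:
    predictors = list(METRIC_NAMES)
    univariate, models, cv = {}, {}, {}
    for group, tab in tables.items():
        tab = tab.dropna(subset=["yield_kg_ha"])
        uni_rows = []
        for name in predictors + ["maxr2_ndvi"]:
            fit = modeling.fit_univariate_best(tab[name], tab["yield_kg_ha"],
                                               predictor=name)
            uni_rows.append({"predictor": name, "family": fit.family,
                             "r2": fit.r2, "significant": fit.significant})
        univariate[group] = pd.DataFrame(uni_rows)
        models[(group, "pheno")] = modeling.stepwise_regression(
            tab, predictors, "yield_kg_ha", p_enter=params.p_enter,
            p_remove=params.p_remove, vif_cap=params.vif_cap)
        models[(group, "pheno_maxr2")] = modeling.stepwise_regression(
            tab, predictors + ["maxr2_ndvi"], "yield_kg_ha",
            p_enter=params.p_enter, p_remove=params.p_remove,
            vif_cap=params.vif_cap)
        variables = models[(group, "pheno")].variables
        if variables and tab["year"].nunique() >= 3:
            cv[group] = modeling.loyo_cv(tab, variables, "yield_kg_ha",
                                         r2_method=params.cv_r2_method)
    return univariate, models, cv


def run_pipeline(data, params: PipelineParams | None = None,
                 outdir=None) -> PipelineResult:
    """Run all stages and return tables, models and the run manifest.

    ``data`` may be a :class:`SimConfig` (a panel is simulated first), a
    :class:`Panel`, or a directory holding ``composites.csv``,
    ``fractions.csv`` and ``yields.csv``.  Identical data, parameters and
    seed reproduce identical outputs.
    """
    params = params or PipelineParams()
    if isinstance(data, SimConfig):
        panel = simulate_panel(data)
        seed = data.seed
    elif isinstance(data, Panel):
        panel, seed = data, data.config.seed
    else:
        d = Path(data)
        panel = Panel(
            composites=pd.read_csv(d / "composites.csv"),
            fractions=pd.read_csv(d / "fractions.csv"),
            yields=pd.read_csv(d / "yields.csv"),
            truth=None, config=None)
        seed = None
    manifest = RunManifest(config_hash=_config_hash(
        panel.config if panel.config is not None else data, params), seed=seed)

    t0 = time.perf_counter()
    adjusted = _prep_stage(panel.composites, params, manifest)
    manifest.timings["prep"] = time.perf_counter() - t0
    n_pixel_years = panel.composites.groupby(
        ["county_id", "pixel_id", "year"]).ngroups
    manifest.row_counts["pixel_years_in"] = n_pixel_years
    manifest.row_counts["pixel_years_prepped"] = len(adjusted)

    t0 = time.perf_counter()
    county_series, county_sd = _aggregate_stage(adjusted, panel.fractions,
                                                params, manifest)
    manifest.timings["aggregate"] = time.perf_counter() - t0
    manifest.row_counts["county_years_aggregated"] = len(county_sd)

    t0 = time.perf_counter()
    dates, phases_map = _phenology_stage(county_series, county_sd, manifest)
    manifest.timings["phenology"] = time.perf_counter() - t0
    manifest.row_counts["county_years_dated"] = len(dates)

    t0 = time.perf_counter()
    tables, selections = _metrics_stage(phases_map, county_series,
                                        panel.yields, params)
    univariate, models, cv = _modeling_stage(tables, params)
    manifest.timings["metrics_modeling"] = time.perf_counter() - t0

    result = PipelineResult(county_series=county_series, county_sd=county_sd,
                            dates=dates, metrics_tables=tables,
                            maxr2=selections, univariate=univariate,
                            models=models, cv=cv, manifest=manifest)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.county_series.to_csv(outdir / "county_daily.csv", index=False)
    result.dates.to_csv(outdir / "dates.csv", index=False)
    result.metrics_tables["whole"].to_csv(outdir / "metrics.csv", index=False)
    (outdir / "report.txt").write_text(format_report(result))


def format_report(result: PipelineResult) -> str:
    """Plain-text model summary: univariate screen, stepwise fits, CV."""
    lines = []
    for group in REGION_GROUPS:
        lines.append(f"== {group} ==")
        lines.append("univariate R2 (best family):")
        for r in result.univariate[group].itertuples():
            star = " *" if r.significant else ""
            lines.append(f"  {r.predictor:<11} {r.family:<12} {r.r2:6.3f}{star}")
        for kind in ("pheno", "pheno_maxr2"):
            m = result.models[(group, kind)]
            eq = " + ".join(f"{m.params[v]:+.2f}*{v}" for v in m.variables)
            lines.append(f"stepwise [{kind}]: R2={m.r2:.3f}  n={m.n}")
            lines.append(f"  Y = {m.params.get('const', float('nan')):.2f} {eq}")
            if len(m.vif):
                lines.append(f"  max VIF = {m.vif.max():.2f}")
        if group in result.cv:
            s = result.cv[group].summary
            lines.append(f"LOYO-CV: median R2={s['r2_median']:.3f}, "
                         f"median RMSE={s['rmse_median']:.1f} kg/ha")
        lines.append("")
    man = result.manifest
    lines.append(f"rows: {man.row_counts}; dropped: {len(man.dropped)}")
    return "\n".join(lines)
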