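"""Reusable recovery studies on synthetic panels.

These are the package's own benchmark experiments: each builds synthetic
data with known truth, runs the relevant part of the pipeline, and
returns per-case recovery errors, so that extraction accuracy and
end-to-end model recovery can be quantified reproducibly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .phenology import extract_phenology
from .pipeline import PipelineParams, run_pipeline
from .prep import DailySeries, detect_growing_season, phenologically_adjust
from .synthetic import (DoubleLogisticParams, SimConfig, double_logistic,
                        simulate_panel)

__all__ = ["true_county_daily", "phenology_recovery", "end_to_end_recovery"]


def true_county_daily(panel, day_grid=None) -> dict:
    """Noise-free county curves: fraction-weighted means of pure pixels.

    Returns ``{(county_id, year): DailySeries}`` on the calendar axis —
    the ideal input the extraction stage would see with perfect
    compositing, used to test stage-date extraction in isolation.
    """
    cfg = panel.config
    day_grid = np.arange(1, 366) if day_grid is None else np.asarray(day_grid)
    fr = panel.fractions.set_index(["county_id", "pixel_id"])["corn_fraction"]
    out = {}
    for (c, y), grp in panel.truth.pixel_params.groupby(["county_id", "year"]):
        w = fr.loc[list(zip(grp["county_id"], grp["pixel_id"]))].to_numpy()
        pure = w > cfg.purity_threshold
        if not pure.any():
            continue
        curves = np.vstack([
            double_logistic(day_grid, DoubleLogisticParams(
                r.base, r.amplitude, r.rise_midpoint, r.rise_rate,
                r.fall_midpoint, r.fall_rate))
            for r in grp[pure].itertuples()])
        ws = w[pure] / w[pure].sum()
        out[(c, y)] = DailySeries(c, y, day_grid, ws @ curves)
    return out


def phenology_recovery(n_counties: int = 50, seed: int = 0,
                       pixels_per_county: int = 6) -> pd.DataFrame:
    """Stage-date recovery on noise-free county curves.

    Simulates ``n_counties`` single-year counties without noise or cloud
    dropout, extracts the five stage dates from each county's true
    (fraction-weighted) curve, and returns the signed errors in days
    against the analytic truth.
    """
    cfg = SimConfig(n_counties=n_counties, pixels_per_county=pixels_per_county,
                    years=(2015,), noise_sd=0.0, dropout_prob=0.0, seed=seed)
    panel = simulate_panel(cfg)
    truth = panel.truth.county_truth.set_index(["county_id", "year"])
    rows = []
    for (c, y), series in true_county_daily(panel).items():
        season = detect_growing_season(series)
        adj = phenologically_adjust(series, season)
        dates, _, _ = extract_phenology(adj)
        t = truth.loc[(c, y)]
        rows.append({
            "county_id": c, "year": y, "sd_err": season.sd - t["true_sd"],
            **{f"{k}_err": season.sd + v - t["true_" + k]
               for k, v in dates.as_dict().items()},
            "ordered": dates.v1 <= dates.v6 <= dates.vt <= dates.r4 <= dates.r6})
    return pd.DataFrame(rows)


def end_to_end_recovery(n_replicates: int = 50, base_seed: int = 0,
                        params: PipelineParams | None = None) -> pd.DataFrame:
    """Full-pipeline model recovery over seeded replicates.

    For each replicate a default-sized panel (300 county-years) is
    simulated with yields generated from four true metrics at generating
    R^2 0.65; the whole pipeline runs and the whole-region stepwise model
    is compared with the generator: fitted R^2, whether every retained
    variable that the generator uses has the generating sign, and the
    largest variance inflation factor.
    """
    rows = []
    for i in range(n_replicates):
        cfg = SimConfig(seed=base_seed + i)
        panel = simulate_panel(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(panel, params=params)
        model = res.models[("whole", "pheno")]
        gen = panel.truth.generating
        gen_betas = {k: v for k, v in gen["betas"].items() if k != "intercept"}
        overlap = [v for v in model.variables if v in gen_betas]
        signs_ok = all(np.sign(model.params[v]) == np.sign(gen_betas[v])
                       for v in overlap)
        rows.append({"seed": cfg.seed, "fitted_r2": model.r2,
                     "generating_r2": gen["generating_r2"],
                     "n_selected": len(model.variables),
                     "n_overlap": len(overlap), "signs_ok": bool(signs_ok),
                     "max_vif": float(model.vif.max()) if len(model.vif)
                     else 1.0, "n": model.n})
    return pd.DataFrame(rows)
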