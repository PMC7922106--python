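"""Generator: seasonal curves, compositing, yields, panel reproducibility."""

import numpy as np
import pandas as pd
import pytest

from phenoyield.errors import InvalidInputError
from phenoyield.prep import DailySeries
from phenoyield.synthetic import (DoubleLogisticParams, SimConfig,
                                  analytic_stage_dates, double_logistic,
                                  metrics_from_dates, simulate_composites,
                                  simulate_panel, simulate_pixel_curve,
                                  simulate_yields)

DAY = np.arange(1, 366)


class TestPixelCurve:
    def test_shape_limits(self, season_params):
        y = simulate_pixel_curve(season_params, DAY)
        assert y.max() == pytest.approx(0.8, abs=0.01)
        assert DAY[np.argmax(y)] == pytest.approx(205, abs=5)
        assert y[0] == pytest.approx(0.2, abs=1e-3)
        assert y[-1] == pytest.approx(0.2, abs=1e-3)
        assert np.all((y >= -1) & (y <= 1))

    def test_zero_amplitude_flat(self):
        p = DoubleLogisticParams(0.2, 0.0, 160, 0.15, 250, 0.12)
        assert np.allclose(simulate_pixel_curve(p, DAY), 0.2)

    def test_inflection_at_rise_midpoint(self, season_params):
        y = simulate_pixel_curve(season_params, DAY)
        d1 = np.gradient(y)
        assert abs(DAY[np.argmax(d1)] - season_params.rise_midpoint) <= 1

    def test_rejects_out_of_order_midpoints(self):
        with pytest.raises(InvalidInputError):
            DoubleLogisticParams(0.2, 0.6, 250, 0.15, 160, 0.12)

    def test_requires_grid_coverage(self, season_params):
        with pytest.raises(InvalidInputError):
            simulate_pixel_curve(season_params, np.arange(150, 200))


class TestComposites:
    def test_noise_free_equals_window_max(self, daily_curve):
        comp = simulate_composites(daily_curve, 0.0, 0.0, seed=0)
        assert len(comp) == 46  # one 365-day calendar year
        for start, val in zip(comp.doy, comp.ndvi):
            w = (daily_curve.day >= start) & (daily_curve.day <= start + 7)
            assert val == pytest.approx(daily_curve.ndvi[w].max())

    def test_full_dropout_biases_down(self, daily_curve):
        comp = simulate_composites(daily_curve, 0.0, 0.999999, seed=1,
                                   dropout_bias=0.3)
        clean = simulate_composites(daily_curve, 0.0, 0.0, seed=1)
        assert np.all(comp.ndvi <= clean.ndvi - 0.3 + 1e-9)

    def test_mvc_suppresses_negative_dropout_better_than_symmetric_noise(
            self, daily_curve):
        # MVC is built for negatively biased contamination: per-window max
        # discards cloud hits but averages none of the symmetric noise away
        clean = simulate_composites(daily_curve, 0.0, 0.0, seed=0).ndvi
        mad_drop = np.mean(np.abs(
            simulate_composites(daily_curve, 0.0, 0.3, seed=5,
                                dropout_bias=0.3).ndvi - clean))
        rng = np.random.default_rng(5)
        sym = daily_curve.ndvi + rng.choice([-0.3, 0.3], len(daily_curve)) \
            * (rng.random(len(daily_curve)) < 0.3)
        mad_sym = np.mean(np.abs(
            simulate_composites(DailySeries("p", 2015, daily_curve.day, sym),
                                0.0, 0.0, seed=5).ndvi - clean))
        assert mad_drop < mad_sym

    def test_rejects_bad_dropout(self, daily_curve):
        with pytest.raises(InvalidInputError):
            simulate_composites(daily_curve, 0.01, 1.0, seed=0)


class TestAnalyticTruth:
    def test_stage_dates_match_numeric_derivative(self, curve_fn):
        dates = analytic_stage_dates(curve_fn, 1, 365)
        fine = np.arange(1.0, 365.0, 0.05)
        y = curve_fn(fine)
        g = np.gradient(y, fine)
        assert abs(fine[np.argmax(g)] - dates["v6"]) <= 1
        assert abs(fine[np.argmin(g)] - dates["r6"]) <= 1
        seq = [dates[k] for k in ("sd", "v1", "v6", "vt", "r4", "r6", "ed")]
        assert seq == sorted(seq)

    def test_metrics_identity(self, curve_fn):
        dates = analytic_stage_dates(curve_fn, 1, 365)
        m = metrics_from_dates(dates, curve_fn)
        assert m["gp2d"] == pytest.approx(dates["vt"] - dates["v6"])
        # rate * duration reconstructs the NDVI change of each phase
        assert m["gp2r"] * m["gp2d"] == pytest.approx(
            curve_fn(dates["vt"]) - curve_fn(dates["v6"]))
        assert m["gp1r"] > 0 and m["gp2r"] > 0 and m["gp4r"] < 0


class TestYields:
    def _truth(self, n=40, seed=0):
        cfg = SimConfig(n_counties=5, pixels_per_county=3, years=(2014, 2015),
                        noise_sd=0.0, dropout_prob=0.0, seed=seed)
        return simulate_panel(cfg).truth

    def test_noise_free_yields_exactly_linear(self):
        truth = self._truth()
        betas = {"intercept": 1000.0, "gp2d": 50.0, "gp4r": -1e4}
        out = simulate_yields(truth, betas, noise_sd=0.0, seed=0)
        expect = (1000.0 + 50.0 * truth.county_truth["true_gp2d"]
                  - 1e4 * truth.county_truth["true_gp4r"])
        assert np.allclose(out["yield_kg_ha"], expect)

    def test_zero_betas_constant(self):
        truth = self._truth()
        out = simulate_yields(truth, {"intercept": 10000.0}, noise_sd=5.0,
                              seed=3)
        assert np.allclose(out["yield_kg_ha"], 10000.0, atol=25)
        assert out["yield_kg_ha"].std() > 0

    def test_noise_calibration_hits_target_r2(self):
        # the recorded generating R^2 is the realized decomposition of the
        # panel's draws, so it matches the target up to noise-variance
        # sampling error (which shrinks with the number of county-years)
        cfg = SimConfig(n_counties=30, pixels_per_county=3, years=(2014, 2015),
                        noise_sd=0.0, dropout_prob=0.0, seed=0)
        truth = simulate_panel(cfg).truth
        simulate_yields(truth, {"gp2d": 100.0, "gp3d": 50.0}, noise_sd=None,
                        seed=0, target_r2=0.65)
        assert truth.generating["generating_r2"] == pytest.approx(0.65,
                                                                  abs=0.08)

    def test_rejects_nonfinite_betas(self):
        with pytest.raises(InvalidInputError):
            simulate_yields(self._truth(), {"gp2d": np.inf}, 0.0, seed=0)


class TestPanel:
    def test_same_seed_identical(self):
        cfg = SimConfig(n_counties=3, pixels_per_county=2,
                        years=(2015, 2016), seed=11)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        pd.testing.assert_frame_equal(a.composites, b.composites)
        pd.testing.assert_frame_equal(a.yields, b.yields)
        pd.testing.assert_frame_equal(a.truth.county_truth,
                                      b.truth.county_truth)

    def test_row_counts(self):
        cfg = SimConfig(n_counties=5, pixels_per_county=2,
                        years=(2014, 2015, 2016), seed=2)
        panel = simulate_panel(cfg)
        assert len(panel.yields) <= 15
        assert panel.composites.groupby(
            ["county_id", "pixel_id", "year"]).ngroups == 30
        assert set(panel.yields["region_group"]) <= {"semi_arid",
                                                     "non_semi_arid"}

    def test_pixel_truth_dates_ordered(self):
        cfg = SimConfig(n_counties=2, pixels_per_county=2, years=(2015,),
                        seed=4)
        dates = simulate_panel(cfg).truth.pixel_dates()
        cols = ["true_sd", "true_v1", "true_v6", "true_vt", "true_r4",
                "true_r6", "true_ed"]
        arr = dates[cols].to_numpy()
        assert np.all(np.diff(arr, axis=1) >= 0)

    def test_zero_counties_rejected(self):
        with pytest.raises(InvalidInputError):
            SimConfig(n_counties=0)
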