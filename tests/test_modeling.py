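"""Univariate screens, VIF, stepwise selection, LOYO-CV, date agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from phenoyield.errors import InvalidInputError, ModelingError
from phenoyield.modeling import (date_agreement, fit_univariate_best, loyo_cv,
                                 standardize_coefficients, state_mean_dates,
                                 stepwise_regression, vif)


class TestUnivariate:
    def test_exact_linear(self):
        x = np.linspace(1, 10, 30)
        fit = fit_univariate_best(x, 2 * x + 1)
        assert fit.family == "linear" and fit.r2 == pytest.approx(1.0)
        assert fit.significant

    def test_pure_quadratic_on_symmetric_grid(self):
        x = np.linspace(-3, 3, 31)  # symmetric: x and x^2 are orthogonal
        fit = fit_univariate_best(x, x ** 2)
        assert fit.family == "quadratic" and fit.r2 == pytest.approx(1.0)
        lin = sm.OLS(x ** 2, sm.add_constant(x)).fit()
        assert lin.rsquared == pytest.approx(0.0, abs=1e-12)

    def test_logarithmic_wins_on_log_data(self):
        rng = np.random.default_rng(17)
        x = np.linspace(1, 10, 60)
        y = np.log(x) + rng.normal(0, 0.01, 60)
        assert fit_univariate_best(x, y).family == "logarithmic"

    def test_zero_variance_rejected(self):
        with pytest.raises(ModelingError):
            fit_univariate_best(np.ones(10), np.arange(10.0))


class TestVif:
    def test_orthogonal_columns_unity(self):
        x = pd.DataFrame({"a": [1, -1, 1, -1, 1, -1, 1, -1],
                          "b": [1, 1, -1, -1, 1, 1, -1, -1],
                          "c": [1, 1, 1, 1, -1, -1, -1, -1]})
        assert np.allclose(vif(x), 1.0)

    def test_r2_075_gives_four(self):
        # X1 = sqrt(3) * X2 + r with r orthogonal to X2: R_1^2 = 3/4 exactly
        x2 = np.tile([1.0, -1.0], 8)
        r = np.tile([1.0, 1.0, -1.0, -1.0], 4)
        x = pd.DataFrame({"x1": np.sqrt(3) * x2 + r, "x2": x2})
        assert vif(x)["x1"] == pytest.approx(4.0, abs=1e-9)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=(100, 5))
        base[:, 3] = base[:, 0] * 0.8 + rng.normal(0, 0.5, 100)
        x = pd.DataFrame(base, columns=list("abcde"))
        ours = vif(x)
        design = sm.add_constant(x).to_numpy()
        oracle = [variance_inflation_factor(design, i + 1) for i in range(5)]
        assert np.allclose(ours.to_numpy(), oracle, atol=1e-8)

    def test_perfect_collinearity_infinite(self):
        x = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        assert np.isinf(vif(x)).all()


class TestStepwise:
    @staticmethod
    def _bic_best_subset(data, candidates, y_col):
        best, best_bic = [], np.inf
        for k in range(len(candidates) + 1):
            for combo in itertools.combinations(candidates, k):
                x = sm.add_constant(data[list(combo)]) if combo else \
                    pd.DataFrame({"const": np.ones(len(data))},
                                 index=data.index)
                bic = sm.OLS(data[y_col], x).fit().bic
                if bic < best_bic:
                    best, best_bic = list(combo), bic
        return sorted(best)

    def test_single_true_predictor_selected(self):
        rng = np.random.default_rng(21)
        n = 200
        data = pd.DataFrame(rng.normal(size=(n, 5)),
                            columns=[f"x{i}" for i in range(1, 6)])
        data["y"] = data["x1"] + rng.normal(0, 0.1, n)
        model = stepwise_regression(data, [f"x{i}" for i in range(1, 6)], "y")
        assert model.variables == ["x1"]
        assert self._bic_best_subset(data, [f"x{i}" for i in range(1, 6)],
                                     "y") == ["x1"]

    def test_exact_two_variable_model(self):
        rng = np.random.default_rng(22)
        n = 60
        data = pd.DataFrame({"x1": rng.normal(size=n),
                             "x2": rng.normal(size=n)})
        data["y"] = 3.0 * data["x1"] - 2.0 * data["x2"]
        model = stepwise_regression(data, ["x1", "x2"], "y")
        assert sorted(model.variables) == ["x1", "x2"]
        assert model.r2 == pytest.approx(1.0)
        # standardized coefficients proportional to beta * sd(x)
        want = np.array([3.0 * data["x1"].std(ddof=1),
                         -2.0 * data["x2"].std(ddof=1)])
        got = model.std_coefs[["x1", "x2"]].to_numpy()
        assert np.allclose(got / np.linalg.norm(got),
                           want / np.linalg.norm(want))

    def test_duplicated_column_never_enters(self):
        rng = np.random.default_rng(23)
        n = 80
        data = pd.DataFrame({"x1": rng.normal(size=n)})
        data["dup"] = data["x1"]
        data["y"] = 2 * data["x1"] + rng.normal(0, 0.2, n)
        model = stepwise_regression(data, ["x1", "dup"], "y")
        assert model.variables == ["x1"]

    def test_no_signal_returns_intercept_only(self):
        rng = np.random.default_rng(24)
        data = pd.DataFrame({"x1": rng.normal(size=50),
                             "y": rng.normal(size=50)})
        with pytest.warns(UserWarning):
            model = stepwise_regression(data, ["x1"], "y", p_enter=1e-6)
        assert model.variables == []


class TestStandardize:
    def test_zscored_inputs_equal_raw(self):
        rng = np.random.default_rng(31)
        n = 100
        x = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        x = (x - x.mean()) / x.std(ddof=1)
        y = 1.5 * x["a"] - 0.5 * x["b"] + rng.normal(0, 0.3, n)
        y = (y - y.mean()) / y.std(ddof=1)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        std = standardize_coefficients(res.params, x, y)
        assert np.allclose(std, res.params[["a", "b"]])

    def test_unit_change_invariance(self):
        rng = np.random.default_rng(32)
        n = 80
        x = pd.DataFrame({"a": rng.normal(size=n)})
        y = pd.Series(2.0 * x["a"] + rng.normal(0, 0.4, n))
        res1 = sm.OLS(y, sm.add_constant(x)).fit()
        x2 = x * 2.0
        res2 = sm.OLS(y, sm.add_constant(x2)).fit()
        assert res2.params["a"] == pytest.approx(res1.params["a"] / 2)
        s1 = standardize_coefficients(res1.params, x, y)
        s2 = standardize_coefficients(res2.params, x2, y)
        assert s1["a"] == pytest.approx(s2["a"])

    def test_single_predictor_equals_pearson_r(self):
        rng = np.random.default_rng(33)
        n = 120
        x = pd.DataFrame({"a": rng.normal(size=n)})
        y = pd.Series(0.7 * x["a"] + rng.normal(0, 1.0, n))
        res = sm.OLS(y, sm.add_constant(x)).fit()
        std = standardize_coefficients(res.params, x, y)
        assert std["a"] == pytest.approx(np.corrcoef(x["a"], y)[0, 1],
                                         abs=1e-10)


class TestLoyoCv:
    def _table(self, n_per_year=20, years=range(2010, 2016), noise=0.0,
               seed=41):
        rng = np.random.default_rng(seed)
        rows = []
        for yr in years:
            x = rng.normal(size=n_per_year)
            rows.append(pd.DataFrame({
                "year": yr, "x": x,
                "y": 9000 + 800 * x + rng.normal(0, noise, n_per_year)}))
        return pd.concat(rows, ignore_index=True)

    def test_noise_free_perfect_folds(self):
        cv = loyo_cv(self._table(), ["x"], "y")
        assert len(cv.folds) == 6  # one fold per year
        assert np.allclose(cv.folds["r2"], 1.0)
        assert np.allclose(cv.folds["rmse"], 0.0, atol=1e-9)

    def test_permuted_yields_near_zero_skill(self):
        table = self._table(n_per_year=30, years=range(2008, 2019),
                            noise=200.0)
        rng = np.random.default_rng(55)
        table["y"] = rng.permutation(table["y"].to_numpy())
        cv = loyo_cv(table, ["x"], "y")
        assert cv.median_r2 < 0.1

    def test_small_year_skipped_with_warning(self):
        table = self._table()
        table = pd.concat([table, pd.DataFrame(
            {"year": [2020], "x": [0.1], "y": [9000.0]})], ignore_index=True)
        with pytest.warns(UserWarning, match="fold skipped"):
            cv = loyo_cv(table, ["x"], "y")
        assert 2020 not in set(cv.folds["year"])

    def test_rmse_matches_noise_scale_with_constant_generator(self):
        rng = np.random.default_rng(61)
        years = np.repeat(np.arange(2008, 2019), 28)
        table = pd.DataFrame({
            "year": years, "x": rng.normal(size=len(years)),
            "y": 10000 + rng.normal(0, 500.0, len(years))})
        cv = loyo_cv(table, ["x"], "y")
        assert cv.median_rmse == pytest.approx(500.0, rel=0.15)

    def test_needs_three_years(self):
        with pytest.raises(InvalidInputError):
            loyo_cv(self._table(years=[2010, 2011]), ["x"], "y")


class TestDateAgreement:
    def test_identical_and_offset_series(self):
        ref = np.array([140.0, 145.0, 150.0, 155.0, 160.0])
        same = date_agreement(ref, ref)
        assert same["r2"] == pytest.approx(1.0)
        assert same["rmse_days"] == 0.0
        off = date_agreement(ref + 3.0, ref)
        assert off["r2"] == pytest.approx(1.0)
        assert off["rmse_days"] == pytest.approx(3.0)
        assert off["bias_days"] == pytest.approx(3.0)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            date_agreement([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_state_means_match_hand_computation(self):
        df = pd.DataFrame({
            "state": ["IA", "IA", "IL", "IL"], "year": [2015] * 4,
            "v1": [140.0, 150.0, 142.0, 146.0],
            "r6": [260.0, 270.0, 258.0, 262.0]})
        out = state_mean_dates(df, ["v1", "r6"])
        ia = out[out["state"] == "IA"].iloc[0]
        assert ia["v1"] == pytest.approx(145.0)
        assert ia["r6"] == pytest.approx(265.0)
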