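"""Yield regression: univariate screens, stepwise selection, VIF, LOYO-CV.

Per region group (whole / semi-arid / non-semi-arid) the workflow is:

1. a univariate screen of every predictor against yield, keeping the best
   of the linear, quadratic and logarithmic families;
2. forward-backward stepwise multiple linear regression (enter while the
   candidate's partial p-value < p_enter, drop while a retained variable's
   p-value > p_remove), with a variance-inflation-factor guard that keeps
   collinear candidates out;
3. standardized coefficients beta_i * sd(X_i)/sd(Y) to rank variable
   importance across units;
4. leave-one-year-out cross-validation: train on all years but one,
   predict the held-out year, report per-fold R^2 (squared Pearson
   correlation between predicted and observed, by default) and RMSE in
   kg ha^-1.

The variance inflation factor of predictor i is 1/(1 - R_i^2), with R_i^2
the coefficient of determination of X_i regressed on the other predictors;
values below 4 are read as non-collinear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError, ModelingError

__all__ = [
    "UnivariateFit",
    "RegressionModel",
    "CVResult",
    "fit_univariate_best",
    "vif",
    "stepwise_regression",
    "standardize_coefficients",
    "loyo_cv",
    "date_agreement",
    "state_mean_dates",
]


@dataclass(frozen=True)
class UnivariateFit:
    """Best single-predictor yield model among three functional families."""

    predictor: str
    family: str                   # linear | quadratic | logarithmic
    coefficients: np.ndarray      # intercept first
    r2: float
    p_value: float                # overall F-test
    significant: bool             # p < 0.05


@dataclass
class RegressionModel:
    """A fitted multiple linear yield regression.

    ``params`` holds the intercept ('const') and raw coefficients in
    kg ha^-1 per predictor unit; ``std_coefs`` the dimensionless
    standardized coefficients (intercept excluded); ``vif`` one variance
    inflation factor per retained variable.
    """

    variables: list
    params: pd.Series
    std_coefs: pd.Series
    r2: float
    vif: pd.Series
    n: int
    pvalues: pd.Series = field(default=None, repr=False)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(table[self.variables], has_constant="add")
        return x[self.params.index].to_numpy() @ self.params.to_numpy()


@dataclass
class CVResult:
    """Leave-one-year-out cross-validation outcome."""

    folds: pd.DataFrame           # year, n_test, r2, rmse
    summary: dict                 # median / q1 / q3 of r2 and rmse

    @property
    def median_r2(self) -> float:
        return self.summary["r2_median"]

    @property
    def median_rmse(self) -> float:
        return self.summary["rmse_median"]


def fit_univariate_best(x, y, predictor: str = "x") -> UnivariateFit:
    """Best of y~x, y~x+x^2 and y~ln(x) by R^2.

    The logarithmic family is only attempted when all x are positive.
    Reports the overall-F p-value and its significance at p < 0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise InvalidInputError("need matched x, y with n >= 5")
    if np.std(x) == 0:
        raise ModelingError(f"predictor {predictor!r} has zero variance")
    designs = {"linear": np.column_stack([x]),
               "quadratic": np.column_stack([x, x ** 2])}
    if np.all(x > 0):
        designs["logarithmic"] = np.column_stack([np.log(x)])
    best = None
    for family, cols in designs.items():
        res = sm.OLS(y, sm.add_constant(cols)).fit()
        if best is None or res.rsquared > best[1].rsquared:
            best = (family, res)
    family, res = best
    return UnivariateFit(predictor=predictor, family=family,
                         coefficients=np.asarray(res.params),
                         r2=float(res.rsquared),
                         p_value=float(res.f_pvalue),
                         significant=bool(res.f_pvalue < 0.05))


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1/(1 - R_i^2), one per column.

    R_i^2 comes from regressing column i on all remaining columns (with
    intercept).  Perfectly collinear columns get VIF = inf.
    """
    design = pd.DataFrame(design)
    k = design.shape[1]
    if k < 2:
        raise InvalidInputError("VIF needs at least 2 predictors")
    if len(design) <= k + 1:
        raise InvalidInputError("VIF needs n > number of predictors + 1")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=[col]))
        r2 = sm.OLS(design[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def standardize_coefficients(params: pd.Series, table: pd.DataFrame,
                             y: np.ndarray | pd.Series) -> pd.Series:
    """Dimensionless coefficients beta_i * sd(X_i) / sd(Y), intercept dropped."""
    y = np.asarray(y, dtype=float)
    sdy = np.std(y, ddof=1)
    if sdy == 0:
        raise ModelingError("response has zero variance")
    names = [n for n in params.index if n != "const"]
    sdx = table[names].std(ddof=1)
    return params[names] * sdx / sdy


def _fit_ols(table: pd.DataFrame, variables: list, y: pd.Series):
    x = sm.add_constant(table[variables], has_constant="add")
    return sm.OLS(y, x).fit()


def stepwise_regression(table: pd.DataFrame, candidates: list, y_col: str,
                        p_enter: float = 0.05, p_remove: float = 0.10,
                        vif_cap: float = 4.0) -> RegressionModel:
    """Forward-backward stepwise multiple linear regression.

    At each forward step the candidate with the smallest partial p-value
    enters if p < ``p_enter`` and no variance inflation factor of the
    tentative model exceeds ``vif_cap`` (which also keeps duplicated or
    collinear columns out); backward steps drop retained variables whose
    p-value rises above ``p_remove``.  If nothing qualifies, an
    intercept-only model is returned with a warning.
    """
    data = table[list(dict.fromkeys(list(candidates) + [y_col]))].dropna()
    y = data[y_col]
    if len(data) < 5:
        raise InvalidInputError("too few complete cases for regression")
    selected: list = []
    while True:
        changed = False
        # forward
        trial = []
        for rank, cand in enumerate(candidates):
            if cand in selected or data[cand].std() == 0:
                continue
            res = _fit_ols(data, selected + [cand], y)
            trial.append((res.pvalues[cand], rank, cand))
        # best candidate first (ties: earlier candidate); a candidate whose
        # entry would breach the VIF cap is passed over, not terminal
        for p_cand, _, cand in sorted(trial):
            if p_cand >= p_enter:
                break
            tentative = selected + [cand]
            if len(tentative) >= 2:
                v = vif(data[tentative])
                if not bool((v <= vif_cap).all()):
                    continue
            selected = tentative
            changed = True
            break
        # backward
        while len(selected) > 0:
            res = _fit_ols(data, selected, y)
            pv = res.pvalues.drop("const")
            worst = pv.idxmax()
            if pv[worst] > p_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        warnings.warn("no candidate met the entry criterion; "
                      "returning intercept-only model")
        const = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
        res = sm.OLS(y, const).fit()
        return RegressionModel(variables=[], params=res.params,
                               std_coefs=pd.Series(dtype=float),
                               r2=float(res.rsquared),
                               vif=pd.Series(dtype=float), n=len(data),
                               pvalues=res.pvalues)
    res = _fit_ols(data, selected, y)
    v = vif(data[selected]) if len(selected) >= 2 else \
        pd.Series({selected[0]: 1.0}, name="vif")
    return RegressionModel(variables=list(selected), params=res.params,
                           std_coefs=standardize_coefficients(res.params, data, y),
                           r2=float(res.rsquared), vif=v, n=len(data),
                           pvalues=res.pvalues)


def loyo_cv(table: pd.DataFrame, variables: list, y_col: str,
            year_col: str = "year", min_counties: int = 3,
            r2_method: str = "corr", refit_stepwise: bool = False,
            **stepwise_kwargs) -> CVResult:
    """Leave-one-year-out cross-validation of a yield regression.

    For each year the model is trained on all remaining years and used to
    predict the held-out year.  Fold R^2 is the squared Pearson correlation
    between predicted and observed (``r2_method='corr'``) or
    1 - SSE/SST (``r2_method='ss'``); RMSE is in the response's units.
    Folds with fewer than ``min_counties`` test samples are skipped with a
    warning.  With ``refit_stepwise`` the variable selection is re-run
    inside every training fold (``variables`` then act as candidates).
    """
    if r2_method not in ("corr", "ss"):
        raise InvalidInputError("r2_method must be 'corr' or 'ss'")
    data = table[list(dict.fromkeys(list(variables) + [y_col, year_col]))].dropna()
    years = sorted(data[year_col].unique())
    if len(years) < 3:
        raise InvalidInputError("leave-one-year-out needs >= 3 distinct years")
    rows = []
    for yr in years:
        test = data[data[year_col] == yr]
        train = data[data[year_col] != yr]
        if len(test) < min_counties:
            warnings.warn(f"year {yr}: only {len(test)} samples; fold skipped")
            continue
        if refit_stepwise:
            model = stepwise_regression(train, variables, y_col,
                                        **stepwise_kwargs)
            pred = model.predict(test) if model.variables else \
                np.full(len(test), model.params["const"])
        else:
            res = _fit_ols(train, list(variables), train[y_col])
            x = sm.add_constant(test[list(variables)], has_constant="add")
            pred = x[res.params.index].to_numpy() @ res.params.to_numpy()
        obs = test[y_col].to_numpy(dtype=float)
        rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
        if np.std(pred) == 0 or np.std(obs) == 0:
            r2 = 0.0
        elif r2_method == "corr":
            r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
        else:
            sse = float(np.sum((obs - pred) ** 2))
            sst = float(np.sum((obs - obs.mean()) ** 2))
            r2 = 1.0 - sse / sst
        rows.append({"year": yr, "n_test": len(test), "r2": r2, "rmse": rmse})
    folds = pd.DataFrame(rows)
    if folds.empty:
        raise ModelingError("no usable cross-validation fold")
    summary = {}
    for m in ("r2", "rmse"):
        summary[m + "_median"] = float(folds[m].median())
        summary[m + "_q1"] = float(folds[m].quantile(0.25))
        summary[m + "_q3"] = float(folds[m].quantile(0.75))
    return CVResult(folds=folds, summary=summary)


def date_agreement(predicted, reference) -> dict:
    """Agreement between two stage-date series (e.g. satellite vs survey).

    Returns the R^2 of the linear regression of predicted on reference,
    the RMSE in days, and the mean bias (predicted minus reference) for
    1:1-line diagnostics.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise InvalidInputError("date series must have equal length")
    if len(predicted) < 3:
        raise InvalidInputError("need at least 3 paired dates")
    res = stats.linregress(reference, predicted)
    rmse = float(np.sqrt(np.mean((predicted - reference) ** 2)))
    bias = float(np.mean(predicted - reference))
    return {"r2": float(res.rvalue ** 2), "rmse_days": rmse, "bias_days": bias}


def state_mean_dates(dates_table: pd.DataFrame, date_cols: list,
                     group_cols: list = ("state", "year")) -> pd.DataFrame:
    """Unweighted mean of county stage dates per state-year."""
    return (dates_table.groupby(list(group_cols))[list(date_cols)]
            .mean().reset_index())
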