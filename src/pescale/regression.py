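"""Quadratic regressions linking fitted parameters to learning efficiency.

Overall performance error (and, separately, its cross-SD dissimilarity) is
regressed on the adaptation index nu, the learning-rate decay eta, the
initial learning rate alpha1, and their squares:

    Y = b0 + b1 nu + b2 eta + b3 alpha1 + b4 nu^2 + b5 eta^2 + b6 alpha1^2 + e

The linear predictors and the outcome are z-transformed (sample SD) and the
quadratic terms are the *squares of the z-scored* predictors, left
unstandardized. This order is identifiable from the reported regression
tables: with squared z-scores (each with mean (n-1)/n) the fitted intercept
equals -(b4 + b5 + b6)(n-1)/n, an identity those tables satisfy exactly.
It also keeps each quadratic term nearly orthogonal to its linear term, so
the quadratic coefficient isolates curvature. A significant positive nu^2
term is the signature of the U-shaped adaptation-performance relation:
moderate prediction-error scaling helps, exaggerated scaling hurts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "zscore_columns",
    "quadratic_regression",
    "per_sd_regressions",
    "PREDICTORS",
]

PREDICTORS = ("nu", "eta", "alpha1")


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """z-transform every column (mean 0, sample SD 1)."""
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(float)
        sd = np.std(x, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


@dataclass
class RegressionResult:
    """Standardized OLS fit mirroring the quadratic-regression table layout."""

    table: pd.DataFrame  # index: predictors + intercept; beta/se/t/p/CI
    f_statistic: float
    f_pvalue: float
    r2: float
    r2_adj: float
    df_model: int
    df_resid: int
    n: int

    def coef(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def __str__(self) -> str:
        return (
            f"F({self.df_model},{self.df_resid}) = {self.f_statistic:.3f}, "
            f"p = {self.f_pvalue:.4g}, adj R^2 = {self.r2_adj:.3f}\n"
            + self.table.to_string(float_format=lambda v: f"{v:.3f}")
        )


def _design(params: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PREDICTORS if c not in params.columns]
    if missing:
        raise ValueError(f"missing predictor columns: {missing}")
    X = zscore_columns(params[list(PREDICTORS)].astype(float))
    for c in PREDICTORS:
        X[f"{c}2"] = X[c] ** 2  # square of the z-score, not re-standardized
    return X


def quadratic_regression(params: pd.DataFrame, outcome) -> RegressionResult:
    """OLS of a z-scored outcome on z-scored {nu, eta, alpha1} + their squares."""
    y = pd.Series(np.asarray(outcome, float), index=params.index, name="y")
    if len(y) < 8:
        raise ValueError("need at least 8 observations for 6 predictors")
    X = _design(params)
    yz = zscore_columns(y.to_frame())["y"]
    Xc = sm.add_constant(X, prepend=False)
    model = sm.OLS(yz, Xc).fit()
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    ci = model.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "beta": model.params,
            "se": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    ).rename(index={"const": "intercept"})
    order = ["nu", "eta", "alpha1", "nu2", "eta2", "alpha12", "intercept"]
    table = table.reindex([i for i in order if i in table.index])
    return RegressionResult(
        table=table,
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        r2=float(model.rsquared),
        r2_adj=float(model.rsquared_adj),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        n=int(model.nobs),
    )


def per_sd_regressions(
    params: pd.DataFrame, outcomes_by_sd: dict
) -> dict[float, RegressionResult]:
    """Repeat the quadratic regression with each SD level's outcome."""
    return {sd: quadratic_regression(params, y) for sd, y in outcomes_by_sd.items()}
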