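"""Correlation and regression on independent contrasts.

Contrast regressions must pass through the origin: under Brownian motion
the expected contrast is zero, and the direction of each contrast is an
arbitrary choice of which sister is subtracted from which.  All
statistics here are therefore invariant to sign flips of whole rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class CollinearityError(ValueError):
    pass


@dataclass
class RegressionFit:
    """A no-intercept least-squares fit on contrasts."""

    predictors: list[str]
    slopes: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    adj_r_squared: float
    n: int
    rss: float
    response: str = "y"

    @property
    def df_resid(self) -> int:
        return self.n - len(self.predictors)


def origin_regression(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    *,
    predictor_names: Sequence[str] | None = None,
    response: str = "y",
) -> RegressionFit:
    """Least squares through the origin with t tests on n - p df.

    Raises :class:`CollinearityError` when the design is perfectly
    collinear, naming the offending columns.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.atleast_2d(np.asarray(X, dtype=float))
        if Xv.shape[0] == 1 and Xv.size > 2:
            Xv = Xv.T
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = list(predictor_names) if predictor_names is not None else [
            f"x{i}" for i in range(Xv.shape[1])
        ]
    yv = np.asarray(y, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"n={n} contrasts cannot support {p} predictors")
    if np.isnan(yv).any() or np.isnan(Xv).any():
        raise ValueError("missing values in regression inputs")
    rank = np.linalg.matrix_rank(Xv)
    if rank < p:
        raise CollinearityError(
            f"perfectly collinear predictors among {names}"
        )
    model = sm.OLS(yv, Xv)  # no constant: regression through the origin
    fit = model.fit()
    return RegressionFit(
        predictors=names,
        slopes=pd.Series(fit.params, index=names),
        std_errors=pd.Series(fit.bse, index=names),
        t_values=pd.Series(fit.tvalues, index=names),
        p_values=pd.Series(fit.pvalues, index=names),
        adj_r_squared=float(fit.rsquared_adj),
        n=n,
        rss=float(fit.ssr),
        response=response,
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Through-origin Pearson correlation between two contrast vectors."""

    r: float
    p: float
    n: int


def contrast_correlation(
    x: np.ndarray | pd.Series, y: np.ndarray | pd.Series
) -> CorrelationResult:
    """Pearson correlation through the origin, r = Sxy/sqrt(Sxx*Syy).

    The two-sided p value comes from t = r*sqrt((n-1)/(1-r^2)) on n - 1
    degrees of freedom (no mean is estimated, so only one df is lost to
    the association itself).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv):
        raise ValueError("x and y differ in length")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    sxx = float(xv @ xv)
    syy = float(yv @ yv)
    if sxx == 0 or syy == 0:
        raise ValueError("zero sum of squares; correlation undefined")
    r = float(xv @ yv) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 1
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors from through-origin auxiliary regressions.

    VIF_j = 1/(1 - R^2_j), with R^2_j the uncentred R^2 of regressing
    predictor j on the remaining predictors through the origin.  Perfect
    collinearity yields ``inf`` rather than an exception.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        yv = X[col].to_numpy(dtype=float)
        Xv = others.to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        resid = yv - Xv @ beta
        total = float(yv @ yv)
        r2 = 1.0 - float(resid @ resid) / total if total > 0 else 0.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def nested_f_test(fit_small: RegressionFit, fit_full: RegressionFit) -> float:
    """p value of the F test comparing two nested through-origin models."""
    if not set(fit_small.predictors) < set(fit_full.predictors):
        raise ValueError(
            "models are not strictly nested: "
            f"{fit_small.predictors} vs {fit_full.predictors}"
        )
    if fit_small.n != fit_full.n:
        raise ValueError("models were fitted to different numbers of contrasts")
    d_p = len(fit_full.predictors) - len(fit_small.predictors)
    df2 = fit_full.df_resid
    f = ((fit_small.rss - fit_full.rss) / d_p) / (fit_full.rss / df2)
    return float(stats.f.sf(f, d_p, df2))
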