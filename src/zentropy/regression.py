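"""Logarithmic regression linking indices to entropies.

Fits the model ``Y = a·ln X + b`` by ordinary least squares — a linear fit
of Y on the natural log of X — and reports the statistic set conventionally
printed alongside it: correlation coefficient R, coefficient of
determination R², standard error of the regression S_E, regression sum of
squares SS, regression degrees of freedom df (= 1 for a simple regression)
and the F statistic.

For the CuF₂ family the canonical use pairs each index series
``I(k, k)`` with its entropy series ``ENT_I(k, k)`` over square lattices
``k = 1..8`` (eight observations per fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .descriptors import WEIGHT_NAMES, index_closed_form
from .entropy import entropy_closed_form

__all__ = ["LogModelFit", "fit_log_model", "family_series", "build_model_table"]


@dataclass(frozen=True)
class LogModelFit:
    """Coefficients and statistics of a fitted ``Y = a·ln X + b`` model."""

    a: float  # slope on ln X
    b: float  # intercept
    r: float  # correlation coefficient, sign matching the slope
    r2: float  # coefficient of determination
    se: float  # standard error of the regression, sqrt(RSS / (n − 2))
    ss_reg: float  # regression (model) sum of squares
    ss_total: float  # total sum of squares (reported for comparison)
    df: int  # regression degrees of freedom (1)
    f: float  # F statistic, SS_reg / (RSS / (n − 2))
    n_obs: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.log(x) + self.b


def fit_log_model(x: Sequence[float], y: Sequence[float]) -> LogModelFit:
    """Least-squares fit of ``y = a·ln x + b``.

    Requires at least 3 observations, all ``x`` strictly positive and
    non-constant.  The linear algebra is delegated to statsmodels OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("all x values must be strictly positive for ln x")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise ValueError("x is constant; the slope is unidentifiable")

    res = sm.OLS(y, sm.add_constant(lx)).fit()
    b, a = res.params
    r2 = float(res.rsquared)
    return LogModelFit(
        a=float(a),
        b=float(b),
        r=math.copysign(math.sqrt(r2), a),
        r2=r2,
        se=float(np.sqrt(res.mse_resid)),
        ss_reg=float(res.ess),
        ss_total=float(res.centered_tss),
        df=int(res.df_model),
        f=float(res.fvalue),
        n_obs=int(x.size),
    )


def family_series(name: str, kmin: int = 1, kmax: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """(index, entropy) series of descriptor ``name`` on CuF₂(k, k), k = kmin..kmax."""
    ks = range(kmin, kmax + 1)
    x = np.array([index_closed_form(k, k, name).value for k in ks])
    y = np.array([entropy_closed_form(k, k, name).value for k in ks])
    return x, y


def build_model_table(
    kmin: int = 1,
    kmax: int = 8,
    names: Sequence[str] = WEIGHT_NAMES,
) -> pd.DataFrame:
    """One fitted log model per (index, entropy) pair over square lattices.

    Columns mirror the conventional regression-table layout: Model, R, R²,
    SE, SS, df, F (plus the unrounded coefficients).
    """
    rows = []
    for name in names:
        x, y = family_series(name, kmin, kmax)
        fit = fit_log_model(x, y)
        rows.append(
            {
                "model": f"ENT_{name} = {fit.a:.3f} log({name}) {fit.b:+.3f}",
                "a": fit.a,
                "b": fit.b,
                "R": fit.r,
                "R2": fit.r2,
                "SE": fit.se,
                "SS": fit.ss_reg,
                "SS_total": fit.ss_total,
                "df": fit.df,
                "F": fit.f,
                "n_obs": fit.n_obs,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(list(names), name="pair"))
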