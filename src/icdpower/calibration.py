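"""Estimate the per-code decay parameters delta and epsilon from observed tables.

Both decay laws are log-linear, so ordinary least squares on the log scale
is exact on noiseless model data:

* case-count attrition: ``ln n_x = ln n1 - x ln(1+epsilon)`` — slope and
  intercept free;
* misclassification decay: ``ln(1 - PPV(x)) = x ln(1-delta)`` — forced
  through the origin, because ``f(0) = 1`` exactly (a zero-instance
  "definition" selects population draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["CalibrationFit", "fit_epsilon", "fit_delta"]


@dataclass(frozen=True)
class CalibrationFit:
    """Result of one log-scale least-squares calibration fit.

    ``estimate`` is the decay parameter (delta-hat or epsilon-hat);
    ``intercept`` the fitted log-scale intercept (for the epsilon fit,
    ``exp(intercept)`` recovers the anchor case count n1; the delta fit has
    none); ``r_squared`` the goodness of fit on the regression scale;
    ``residuals`` the per-point log-scale residuals.
    """

    parameter: str
    estimate: float
    intercept: float | None
    r_squared: float
    residuals: np.ndarray
    n_points: int

    @property
    def n1_hat(self) -> float:
        """Anchor case count implied by the epsilon fit's intercept."""
        if self.intercept is None:
            raise ValueError("this fit has no intercept")
        return math.exp(self.intercept)

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "estimate": self.estimate,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def _as_table(table, cols: tuple[str, str]) -> pd.DataFrame:
    df = pd.DataFrame(table)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table must have columns {cols}, missing {missing}")
    return df


def fit_epsilon(counts) -> CalibrationFit:
    """Fit the attrition rate epsilon from a (x, n_x) threshold-count table.

    OLS of ``ln n_x`` on ``x`` (with intercept); ``epsilon-hat =
    exp(-slope) - 1`` and ``n1-hat = exp(intercept)``. Exact on noiseless
    model data.
    """
    df = _as_table(counts, ("x", "n_x"))
    if df["x"].nunique() < 2:
        raise ValueError("need at least 2 distinct x values to fit epsilon")
    if (df["n_x"] <= 0).any():
        raise ValueError("all case counts n_x must be positive")
    y = np.log(df["n_x"].to_numpy(dtype=float))
    X = sm.add_constant(df["x"].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    r2 = float(res.rsquared)
    if math.isnan(r2):  # constant counts: perfect flat fit
        r2 = 1.0
    return CalibrationFit(
        parameter="epsilon",
        estimate=math.exp(-slope) - 1.0,
        intercept=float(intercept),
        r_squared=r2,
        residuals=np.asarray(res.resid),
        n_points=len(df),
    )


def fit_delta(ppv_table) -> CalibrationFit:
    """Fit the misclassification decay delta from a (x, ppv) chart-review table.

    Through-origin OLS of ``ln(1 - ppv)`` on ``x``; ``delta-hat =
    1 - exp(slope)``. A saturated point (ppv = 1) has no finite log
    residual and must be excluded by the caller.
    """
    df = _as_table(ppv_table, ("x", "ppv"))
    if df["x"].nunique() < 2:
        raise ValueError("need at least 2 distinct x values to fit delta")
    ppv = df["ppv"].to_numpy(dtype=float)
    if ((ppv <= 0.0) | (ppv >= 1.0)).any():
        raise ValueError(
            "all ppv values must lie strictly in (0, 1); "
            "exclude saturated points (ppv = 1) before fitting"
        )
    y = np.log(1.0 - ppv)
    X = df["x"].to_numpy(dtype=float)[:, None]
    res = sm.OLS(y, X).fit()  # no constant: f(0) = 1 is exact in the model
    slope = float(res.params[0])
    return CalibrationFit(
        parameter="delta",
        estimate=1.0 - math.exp(slope),
        intercept=None,
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        n_points=len(df),
    )
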