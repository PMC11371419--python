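"""Simple-regression summary shared by the bias check and reuse analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RegressionFit", "fit_ols"]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with the usual one-predictor F summary."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple
    p: float
    n: int

    def __str__(self) -> str:  # compact, table-friendly
        return (
            f"slope={self.slope:.6g} R2={self.r_squared:.4g} "
            f"F_{self.df[0]},{self.df[1]}={self.f_stat:.4g} P={self.p:.4g}"
        )


def fit_ols(x, y) -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x`` (single predictor).

    A constant response is fit with slope 0 and R^2 = 0 by convention; a
    constant predictor is an error.  For one predictor F equals t^2 and the
    F-test p equals the two-sided slope t-test p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y[0]), 0.0, 0.0, (1, n - 2), 1.0, n)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0 - 1e-15:
        f = np.inf
        p = 0.0
        r2 = min(r2, 1.0)
    else:
        f = (n - 2) * r2 / (1.0 - r2)
        p = float(res.pvalue)
    return RegressionFit(
        float(res.slope), float(res.intercept), r2, float(f), (1, n - 2), p, n
    )
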