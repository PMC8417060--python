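"""Ordinary least-squares simple linear fit with the result fields used throughout."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import ValidationError


@dataclass(frozen=True)
class LinearFitResult:
    """y = slope * x + intercept, with plain (not adjusted) R^2 = r^2."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    pearson_r: float = float("nan")
    degenerate: bool = False  # zero variance in the predictor

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def linear_fit(x, y) -> LinearFitResult:
    """OLS of y on x via scipy.stats.linregress; >= 3 points required.

    A constant predictor yields a degenerate-flagged result (slope NaN), not
    an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError(f"linear fit needs >= 3 points, got {len(x)}")
    if np.ptp(x) == 0:
        return LinearFitResult(
            slope=float("nan"), intercept=float(np.mean(y)), r_squared=float("nan"),
            p_value=float("nan"), n=len(x), degenerate=True,
        )
    if np.ptp(y) == 0:
        # flat response: slope 0 explains nothing, define R^2 = r = 0
        return LinearFitResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0,
            n=len(x), pearson_r=0.0,
        )
    res = stats.linregress(x, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=len(x),
        pearson_r=float(res.rvalue),
    )
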