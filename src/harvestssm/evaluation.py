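"""External-comparison analytics.

Catch-per-unit-effort (CPUE), ordinary least-squares trend comparison
between an abundance trajectory and the CPUE index, and a numeric
credible-interval coverage check against independent point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrendComparison", "cpue", "interval_covers", "trend_regression"]


@dataclass(frozen=True)
class TrendComparison:
    """OLS fit of one yearly series on another."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    df: int


def cpue(O_y, permits_y) -> np.ndarray:
    """Catch per unit effort: annual harvest / annual permits issued."""
    O_y = np.asarray(O_y, dtype=float)
    permits_y = np.asarray(permits_y, dtype=float)
    if O_y.shape != permits_y.shape:
        raise ValueError("harvest and permit series must have equal length")
    if np.any(permits_y <= 0):
        raise ValueError("permit counts must be positive")
    return O_y / permits_y


def trend_regression(x, y) -> TrendComparison:
    """OLS of ``y`` on ``x`` with R^2, two-sided slope p-value, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least three points for a trend regression")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("series must not contain missing values")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant; trend regression is degenerate")
    fit = stats.linregress(x, y)
    return TrendComparison(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        df=x.size - 2,
    )


def interval_covers(summary: pd.DataFrame, year: int, external_estimate: float,
                    parameter_prefix: str = "N_total") -> bool:
    """True iff the external point lies inside the model's 95% CrI for ``year``.

    ``summary`` is a :func:`~harvestssm.inference.posterior_summary` frame;
    interval endpoints are inclusive.
    """
    key = f"{parameter_prefix}_{year}"
    if key not in summary.index:
        raise KeyError(f"year {year} not present in the posterior summary")
    row = summary.loc[key]
    return bool(row["cri_2.5"] <= external_estimate <= row["cri_97.5"])
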