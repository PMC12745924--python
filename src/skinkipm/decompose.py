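"""Classical additive seasonal decomposition and variance-share attribution.

Monthly series (estimated survival, monthly lambda) are split into
trend + seasonal + residual with the classical moving-average method: the
trend is a centred 12-month moving average, the seasonal component is the
month-wise mean of the detrended series re-centred to zero, and the residual
is the remainder.  The share of temporal variation attributed to each
component is its variance divided by the summed component variances over the
months where all three are defined — the three shares are nonnegative and
sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.seasonal import seasonal_decompose

__all__ = ["DecompositionResult", "decompose", "variance_shares"]


@dataclass
class DecompositionResult:
    observed: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray
    period: int

    @property
    def shares(self):
        return variance_shares(self)


def decompose(series, period=12):
    """Additive moving-average decomposition of a monthly series.

    The trend is undefined (NaN) in the first and last ``period // 2``
    months, where the centred window does not fit.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 2 * period:
        raise ValueError(
            f"series of length {x.size} is shorter than two periods ({2 * period})"
        )
    res = seasonal_decompose(pd.Series(x), model="additive", period=period)
    return DecompositionResult(
        observed=x,
        trend=res.trend.to_numpy(),
        seasonal=res.seasonal.to_numpy(),
        residual=res.resid.to_numpy(),
        period=period,
    )


def variance_shares(result: DecompositionResult):
    """Fractions of temporal variation due to (seasonal, trend, residual).

    Computed as normalised component variances over the months where the
    trend is defined.  A constant series has no variation to attribute and
    raises.
    """
    ok = np.isfinite(result.trend) & np.isfinite(result.residual)
    parts = {
        "seasonal": float(np.var(result.seasonal[ok])),
        "trend": float(np.var(result.trend[ok])),
        "residual": float(np.var(result.residual[ok])),
    }
    total = sum(parts.values())
    if total <= 0:
        raise ValueError("series has zero variance; shares are undefined")
    return {k: v / total for k, v in parts.items()}
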