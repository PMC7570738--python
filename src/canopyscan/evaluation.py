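"""Accuracy reporting: regression of estimated on measured values.

Validation of every estimator follows the same recipe: regress the
estimated quantity (y) on the measured one (x), report the slope,
intercept and R², and compute RMSE directly on the paired raw values,

    RMSE = sqrt(mean((estimated_i - measured_i)^2)),

not on the residuals of the fitted line — so a well-correlated but
biased estimator still shows a large RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AccuracyReport", "accuracy", "accuracy_table"]


@dataclass(frozen=True)
class AccuracyReport:
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int


def accuracy(measured, estimated) -> AccuracyReport:
    """Regression accuracy between paired measured and estimated vectors.

    OLS of estimated on measured yields slope/intercept/R²; RMSE is the
    root mean square of the raw pairwise differences, in the units of
    the measured quantity.
    """
    x = np.asarray(measured, dtype=np.float64).ravel()
    y = np.asarray(estimated, dtype=np.float64).ravel()
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} measured vs {len(y)} estimated")
    if len(x) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("measured values have zero variance; R² undefined")
    res = stats.linregress(x, y)
    rmse = float(np.sqrt(np.mean((y - x) ** 2)))
    return AccuracyReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        rmse=rmse,
        n=len(x),
    )


def accuracy_table(
    datasets: Mapping[str, Tuple[Sequence[float], Sequence[float]]],
) -> pd.DataFrame:
    """One accuracy row per named (measured, estimated) dataset.

    Datasets that fail (mismatched lengths, constant measured values)
    yield a row with NaN statistics and the error text in an ``error``
    column instead of aborting the whole table.
    """
    rows = []
    for name, (measured, estimated) in datasets.items():
        row: dict = {"dataset": name}
        try:
            rep = accuracy(measured, estimated)
            row.update(
                slope=rep.slope,
                intercept=rep.intercept,
                r_squared=rep.r_squared,
                rmse=rep.rmse,
                n=rep.n,
                error="",
            )
        except ValueError as exc:
            row.update(
                slope=np.nan,
                intercept=np.nan,
                r_squared=np.nan,
                rmse=np.nan,
                n=len(measured),
                error=str(exc),
            )
        rows.append(row)
    columns = ["dataset", "slope", "intercept", "r_squared", "rmse", "n", "error"]
    return pd.DataFrame(rows, columns=columns)
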