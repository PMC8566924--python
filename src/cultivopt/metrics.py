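"""Regression performance indices: R², RMSE and mean bias error.

R² is the conventional coefficient of determination
``1 − Σ(y−ŷ)² / Σ(y−ȳ)²``; RMSE is ``√(Σ(y−ŷ)²/n)``; MBE is the signed mean
``(1/n)Σ(ŷ−y)`` with positive values meaning overprediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float
    mbe: float
    n: int


def compute_metrics(observed, predicted) -> MetricSet:
    """Compute R²/RMSE/MBE for a pair of equal-length vectors.

    Raises
    ------
    MetricError
        On length mismatch, fewer than two points, or non-finite values.
        A constant observed vector yields NaN R² (undefined) while RMSE
        and MBE are still computed.
    """
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise MetricError(
            f"length mismatch: observed {y.size}, predicted {yhat.size}"
        )
    if y.size < 2:
        raise MetricError("need at least two observations")
    if not (np.isfinite(y).all() and np.isfinite(yhat).all()):
        raise MetricError("non-finite values in input")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    resid = y - yhat
    ss_res = float(np.sum(resid**2))
    # R² is undefined for a constant observed vector; RMSE and MBE are not
    return MetricSet(
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        rmse=float(np.sqrt(ss_res / y.size)),
        mbe=float(np.mean(yhat - y)),
        n=int(y.size),
    )
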