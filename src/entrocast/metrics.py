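"""Six-index forecast-error suite for concentration series.

The suite follows the evaluation conventions common in Chinese air-quality
combination-forecasting work; three points deserve note because several
variants circulate in the literature:

* **MPE** here is the mean *absolute* relative error (a MAPE); the
  traditional name is kept for continuity with the index table it implements.
* **Theil's U** uses relative errors ``(y - ŷ)/y`` in the numerator and the
  root-mean-square levels of both series in the denominator — not the
  classical absolute-error numerator.
* Standard deviations in the variance ratio are **population** standard
  deviations (divisor ``n``).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .series import DailySeries

__all__ = ["MetricReport", "evaluate_metrics"]


@dataclass(frozen=True)
class MetricReport:
    """The six error indexes for one (actual, predicted) pair.

    ``mae`` and ``rmse`` are in µg/m³; the remaining four are dimensionless.
    All six are zero iff the prediction is exact, and ``mae <= rmse`` always.
    """

    mae: float
    mpe: float
    rmse: float
    theil_u: float
    bias_ratio: float
    variance_ratio: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_values(x) -> np.ndarray:
    if isinstance(x, DailySeries):
        return x.values
    return np.asarray(x, dtype=float)


def evaluate_metrics(actual, predicted) -> MetricReport:
    """Evaluate the six error indexes of ``predicted`` against ``actual``.

    Parameters
    ----------
    actual
        Observed values, strictly positive (relative indexes divide by them).
    predicted
        Forecast values, same length.

    Returns
    -------
    MetricReport
        MAE, MPE (mean absolute relative error), RMSE, Theil inequality
        coefficient (relative-error numerator), bias ratio
        ``(ȳ − ŷ̄)² / MSE`` and variance ratio ``(s_y − s_ŷ)² / MSE`` with
        population standard deviations.
    """
    y = _as_values(actual)
    yhat = _as_values(predicted)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"shape mismatch: actual {y.shape}, predicted {yhat.shape}")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 points to evaluate")
    if np.any(y <= 0):
        bad = int(np.flatnonzero(y <= 0)[0])
        raise ValueError(f"actual value {y[bad]} at position {bad} is not positive")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite input")

    err = y - yhat
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    mpe = float(np.mean(np.abs(err) / y))
    rmse = float(np.sqrt(mse))
    theil = float(
        np.sqrt(np.mean((err / y) ** 2))
        / (np.sqrt(np.mean(yhat**2)) + np.sqrt(np.mean(y**2)))
    )
    if mse == 0.0:
        # exact prediction: every numerator is identically zero as well
        bias_ratio = 0.0
        variance_ratio = 0.0
    else:
        bias_ratio = float((y.mean() - yhat.mean()) ** 2 / mse)
        variance_ratio = float((y.std() - yhat.std()) ** 2 / mse)
    return MetricReport(
        mae=mae,
        mpe=mpe,
        rmse=rmse,
        theil_u=theil,
        bias_ratio=bias_ratio,
        variance_ratio=variance_ratio,
        n=n,
    )
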