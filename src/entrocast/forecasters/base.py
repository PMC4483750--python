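"""Common forecast-result container shared by all methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForecastResult"]


@dataclass(frozen=True)
class ForecastResult:
    """One method's in-sample fit and out-of-sample forecasts.

    ``fitted`` is aligned to the training index: position ``t`` holds the
    one-step-ahead prediction of observation ``t`` made from history up to
    ``t − 1``.  Positions with insufficient history (e.g. the first
    ``lag_window`` points of the neural net) are NaN, never zero-filled.
    ``forecasts`` holds exactly the requested number of finite values, in
    µg/m³.  ``params`` records the parameters the fit actually used.
    """

    method: str
    fitted: np.ndarray
    forecasts: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fitted", np.asarray(self.fitted, dtype=float))
        object.__setattr__(self, "forecasts", np.asarray(self.forecasts, dtype=float))
        if not np.all(np.isfinite(self.forecasts)):
            raise ValueError(f"{self.method}: non-finite forecast values")
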