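"""Brown quadratic (triple) exponential smoothing.

Three coupled smoothed statistics track the level of the series and of its
own smoothings::

    S′_t = α x_t + (1 − α) S′_{t−1}
    S″_t = α S′_t + (1 − α) S″_{t−1}
    S‴_t = α S″_t + (1 − α) S‴_{t−1}

and at every step a local quadratic model is read off in closed form::

    a_t = 3S′_t − 3S″_t + S‴_t
    b_t = α [ (6 − 5α)S′_t − (10 − 8α)S″_t + (4 − 3α)S‴_t ] / (2(1 − α)²)
    c_t = α² (S′_t − 2S″_t + S‴_t) / (1 − α)²

The m-step-ahead forecast from the state at time t is the quadratic
extrapolation ``Y_{t+m} = a_t + b_t m + ½ c_t m²``.  The method is exact on
polynomial trends up to degree two and, with a small α (the customary
default is 0.15), heavily damps irregular fluctuation.  All three statistics
are initialized to the mean of the first few observations (3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..series import DailySeries
from .base import ForecastResult

__all__ = ["EsmState", "EsmFit", "fit_esm", "forecast_esm"]

DEFAULT_ALPHA = 0.15


def _coefficients(alpha: float, s1: float, s2: float, s3: float) -> tuple[float, float, float]:
    a = 3 * s1 - 3 * s2 + s3
    om = (1 - alpha) ** 2
    b = alpha * ((6 - 5 * alpha) * s1 - (10 - 8 * alpha) * s2 + (4 - 3 * alpha) * s3) / (2 * om)
    c = alpha**2 * (s1 - 2 * s2 + s3) / om
    return a, b, c


@dataclass(frozen=True)
class EsmState:
    """Smoothing state at one time point: the three statistics plus the
    quadratic coefficients they imply."""

    alpha: float
    s1: float
    s2: float
    s3: float
    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_statistics(cls, alpha: float, s1: float, s2: float, s3: float) -> "EsmState":
        a, b, c = _coefficients(alpha, s1, s2, s3)
        return cls(alpha=alpha, s1=s1, s2=s2, s3=s3, a=a, b=b, c=c)

    def update(self, x: float) -> "EsmState":
        """Absorb one new observation."""
        al = self.alpha
        s1 = al * x + (1 - al) * self.s1
        s2 = al * s1 + (1 - al) * self.s2
        s3 = al * s2 + (1 - al) * self.s3
        return EsmState.from_statistics(al, s1, s2, s3)


@dataclass(frozen=True)
class EsmFit:
    """Result of running the recursions over a whole series."""

    states: tuple[EsmState, ...]  # state after absorbing x_t, t = 0..n−1
    fitted: np.ndarray  # fitted[t] = 1-step forecast of x_t from state t−1; NaN at t=0
    alpha: float
    init_value: float

    @property
    def final_state(self) -> EsmState:
        return self.states[-1]


def fit_esm(series: DailySeries | np.ndarray, alpha: float = DEFAULT_ALPHA, n_init: int = 3) -> EsmFit:
    """Run the three smoothing recursions over the series.

    The initial state (all three statistics equal to the mean of the first
    ``n_init`` observations) acts as the pre-sample prior; the recursion is
    applied at every observation.  ``fitted[t]`` for ``t ≥ 1`` is the
    one-step forecast ``a + b + ½c`` evaluated from the state after
    ``x_{t−1}``; the first position has no usable history and is NaN.
    """
    x = series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if len(x) < n_init:
        raise ValueError(f"need at least n_init={n_init} observations, got {len(x)}")
    init = float(np.mean(x[:n_init]))
    state = EsmState.from_statistics(alpha, init, init, init)
    states: list[EsmState] = []
    fitted = np.full(len(x), np.nan)
    for t, xt in enumerate(x):
        if t > 0:
            prev = states[-1]
            fitted[t] = prev.a + prev.b + 0.5 * prev.c
        state = state.update(float(xt))
        states.append(state)
    return EsmFit(states=tuple(states), fitted=fitted, alpha=alpha, init_value=init)


def forecast_esm(state: EsmState | EsmFit, horizon: int) -> ForecastResult:
    """Quadratic extrapolation ``a + b·m + ½c·m²`` for m = 1..horizon."""
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    fitted = np.empty(0)
    if isinstance(state, EsmFit):
        fitted = state.fitted
        state = state.final_state
    m = np.arange(1, horizon + 1, dtype=float)
    fc = state.a + state.b * m + 0.5 * state.c * m**2
    return ForecastResult(
        method="esm",
        fitted=fitted,
        forecasts=fc,
        params={"alpha": state.alpha, "a": state.a, "b": state.b, "c": state.c},
    )
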