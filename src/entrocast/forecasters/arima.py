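"""ARIMA modelling: stationarity testing, order selection, fitting, forecasting.

The model for the d-th difference W_t of the observed series is the ARMA
recursion ``φ(B) W_t = θ(B) ε_t`` with lag polynomials written as

    φ(B) = 1 − φ₁B − … − φ_p B^p,      θ(B) = 1 − θ₁B − … − θ_q B^q,

i.e. *both* coefficient sets enter with a minus sign.  statsmodels uses the
opposite (plus) sign for the MA polynomial, so MA coefficients are negated
at that boundary; :class:`ArimaSpec` always stores the minus convention.

Estimation delegates to :class:`statsmodels.tsa.arima.model.ARIMA`
(state-space exact Gaussian maximum likelihood — recorded in the parameter
record and held fixed).  Order selection replaces visual ACF/PACF reading
with an information-criterion grid search; the default criterion is BIC,
whose consistency keeps white noise identified as (0, 0, 0), with AIC
available as an option.  Differencing depth is capped at 2, which covers
practical concentration series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import adfuller

from ..series import DailySeries
from .base import ForecastResult

__all__ = [
    "ArimaSpec",
    "ArimaFit",
    "StationarityResult",
    "check_stationarity",
    "select_order",
    "fit_arima",
    "forecast_arima",
]

MAX_D = 2
ESTIMATION_METHOD = "statespace-mle"  # exact Gaussian likelihood; held fixed


def _values(series) -> np.ndarray:
    return series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)


@dataclass(frozen=True)
class ArimaSpec:
    """Estimated ARIMA(p, d, q) parameters.

    ``phi``/``theta`` follow the minus-sign polynomial convention above;
    ``mean`` is the process mean of the (differenced, if d > 0) series and
    ``noise_variance`` the innovation variance σ².
    """

    p: int
    d: int
    q: int
    phi: tuple[float, ...]
    theta: tuple[float, ...]
    mean: float
    noise_variance: float

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q) < 0:
            raise ValueError("orders must be non-negative")
        if self.d > MAX_D:
            raise ValueError(f"d={self.d} exceeds the supported maximum of {MAX_D}")
        if len(self.phi) != self.p or len(self.theta) != self.q:
            raise ValueError("coefficient vectors must match (p, q)")

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass(frozen=True)
class StationarityResult:
    stationary: bool  # ADF rejects a unit root in the undifferenced series
    suggested_d: int  # smallest d <= max_d whose d-th difference passes
    pvalues: tuple[float, ...]  # ADF p-value at each differencing depth tried


def check_stationarity(
    series, significance: float = 0.05, max_d: int = MAX_D
) -> StationarityResult:
    """Augmented Dickey–Fuller unit-root screen with differencing suggestion.

    Returns whether the raw series already rejects a unit root, and the
    smallest differencing depth (≤ ``max_d``) whose difference does.  If no
    depth passes, ``suggested_d`` is ``max_d`` and ``stationary`` reflects
    depth 0 only.
    """
    x = _values(series)
    if len(x) < 20:
        raise ValueError(f"need at least 20 observations for the ADF test, got {len(x)}")
    pvalues: list[float] = []
    suggested = max_d
    for d in range(max_d + 1):
        xd = np.diff(x, n=d) if d else x
        if np.ptp(xd) == 0:  # ADF is undefined on a constant; trivially stationary
            pvalues.append(0.0)
        else:
            pvalues.append(float(adfuller(xd, autolag="AIC")[1]))
        if pvalues[-1] <= significance:
            suggested = d
            break
    return StationarityResult(
        stationary=pvalues[0] <= significance,
        suggested_d=suggested,
        pvalues=tuple(pvalues),
    )


def select_order(
    series,
    max_p: int = 5,
    max_q: int = 5,
    max_d: int = MAX_D,
    ic: str = "bic",
    significance: float = 0.05,
    fixed_order: tuple[int, int, int] | None = None,
) -> tuple[int, int, int]:
    """Pick (p, d, q) by information-criterion grid search.

    ``d`` comes from the stationarity screen (smallest depth ≤ ``max_d``
    passing the ADF test); ``p`` and ``q`` minimize the criterion over the
    grid at that depth.  Ties and near-ties (within 1e-9) keep the smaller
    model, making the result deterministic.  ``fixed_order`` disables
    selection and is returned verbatim (validated only), for pinning a known
    specification.
    """
    if fixed_order is not None:
        p, d, q = fixed_order
        ArimaSpec(p, d, q, (0.0,) * p, (0.0,) * q, 0.0, 1.0)  # validation only
        return (p, d, q)
    if ic not in ("aic", "bic"):
        raise ValueError(f"ic must be 'aic' or 'bic', got {ic!r}")
    if max_p < 0 or max_q < 0:
        raise ValueError("empty search grid")
    x = _values(series)
    if len(x) <= max_p + max_q + 10:
        raise ValueError(f"series of length {len(x)} too short for grid ({max_p}, {max_q})")
    d = check_stationarity(x, significance=significance, max_d=max_d).suggested_d
    best_val = np.inf
    best: tuple[int, int, int] | None = None
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ARIMA(x, order=(p, d, q), trend="c" if d == 0 else "n").fit()
                val = res.aic if ic == "aic" else res.bic
            except (np.linalg.LinAlgError, ValueError):
                continue
            if val < best_val - 1e-9:
                best_val, best = val, (p, d, q)
    if best is None:
        raise ValueError("no candidate model could be estimated")
    return best


def fit_arima(series, order: tuple[int, int, int]) -> "ArimaFit":
    """Fit ARIMA(p, d, q) by exact Gaussian maximum likelihood.

    A constant input is flagged with a degenerate-input warning.  Estimates
    on or outside the stationarity/invertibility boundary are flagged with a
    warning, never silently returned.  Residual whiteness is screened with a
    Ljung–Box portmanteau test at lag ``min(10, n // 5)``; failure at the 5%
    level warns (the model may still be useful) rather than erroring.
    """
    x = _values(series)
    p, d, q = order
    ArimaSpec(p, d, q, (0.0,) * p, (0.0,) * q, 0.0, 1.0)  # validate order
    if np.ptp(x) == 0:
        warnings.warn(
            "degenerate input: series is constant; innovation variance ~ 0",
            RuntimeWarning,
            stacklevel=2,
        )
    trend = "c" if d == 0 else "n"
    model = ARIMA(x, order=order, trend=trend)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"ARIMA{order} estimation failed: {exc}") from exc

    phi = tuple(float(v) for v in res.arparams) if p else ()
    # statsmodels returns MA coefficients in the 1 + θB convention; negate.
    theta = tuple(-float(v) for v in res.maparams) if q else ()
    mean = float(res.params[res.param_names.index("const")]) if trend == "c" else 0.0
    sigma2 = float(res.params[res.param_names.index("sigma2")])
    if (p and np.any(np.abs(res.arroots) <= 1.0 + 1e-8)) or (
        q and np.any(np.abs(res.maroots) <= 1.0 + 1e-8)
    ):
        warnings.warn(
            f"ARIMA{order}: estimated roots on or inside the unit circle "
            "(non-stationary or non-invertible estimates)",
            RuntimeWarning,
            stacklevel=2,
        )
    lb_lag = max(1, min(10, len(x) // 5))
    lb_pvalue = np.nan
    resid = np.asarray(res.resid, dtype=float)
    if np.ptp(resid) > 0:
        lb_pvalue = float(acorr_ljungbox(resid, lags=[lb_lag])["lb_pvalue"].iloc[0])
        if lb_pvalue < 0.05:
            warnings.warn(
                f"residuals fail the Ljung-Box whiteness test at lag {lb_lag} "
                f"(p = {lb_pvalue:.4f}); consider re-identifying the order",
                RuntimeWarning,
                stacklevel=2,
            )
    fitted = np.asarray(res.fittedvalues, dtype=float)
    if d > 0:
        fitted = fitted.copy()
        fitted[:d] = np.nan  # undefined until d observations exist
    spec = ArimaSpec(p, d, q, phi, theta, mean, sigma2)
    return ArimaFit(
        spec=spec,
        fitted=fitted,
        resid=resid,
        ljung_box_pvalue=lb_pvalue,
        ljung_box_lag=lb_lag,
        results=res,
    )


@dataclass(frozen=True)
class ArimaFit:
    spec: ArimaSpec
    fitted: np.ndarray
    resid: np.ndarray
    ljung_box_pvalue: float
    ljung_box_lag: int
    results: object = field(repr=False)  # statsmodels results, for forecasting

    @property
    def aic(self) -> float:
        return float(self.results.aic)

    @property
    def bic(self) -> float:
        return float(self.results.bic)


def _params_record(spec: ArimaSpec) -> dict:
    return {
        "order": spec.order,
        "phi": list(spec.phi),
        "theta": list(spec.theta),
        "mean": spec.mean,
        "noise_variance": spec.noise_variance,
        "estimation": ESTIMATION_METHOD,
    }


def forecast_arima(
    fit_or_spec: "ArimaFit | ArimaSpec",
    history=None,
    horizon: int = 1,
) -> ForecastResult:
    """Minimum-MSE forecasts under the fitted model.

    Accepts either an :class:`ArimaFit` (forecasts continue its own training
    series) or a bare :class:`ArimaSpec` plus an explicit ``history``, in
    which case the spec's parameters are applied to the history via the
    state-space filter and extrapolated.  A (0, 0, 0) spec forecasts its
    mean at every step.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    if isinstance(fit_or_spec, ArimaFit):
        fit = fit_or_spec
        fc = np.asarray(fit.results.forecast(horizon), dtype=float)
        return ForecastResult("arima", fit.fitted, fc, _params_record(fit.spec))
    spec = fit_or_spec
    if history is None:
        raise ValueError("forecasting from a bare ArimaSpec requires history")
    x = _values(history)
    trend = "c" if spec.d == 0 else "n"
    model = ARIMA(x, order=spec.order, trend=trend)
    values = {"sigma2": spec.noise_variance}
    if trend == "c":
        values["const"] = spec.mean
    for i, v in enumerate(spec.phi, start=1):
        values[f"ar.L{i}"] = v
    for i, v in enumerate(spec.theta, start=1):
        values[f"ma.L{i}"] = -v  # back to statsmodels' plus convention
    params = np.array([values[name] for name in model.param_names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.filter(params)
    fc = np.asarray(res.forecast(horizon), dtype=float)
    return ForecastResult("arima", np.empty(0), fc, _params_record(spec))
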