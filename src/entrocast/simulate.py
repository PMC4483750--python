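"""Seeded generators for PM2.5-like daily series and ARMA test processes.

The PM2.5 generator emulates the gross structure of daily fine-particulate
records from southern Chinese coastal cities: a positive level around
55 µg/m³, pronounced annual seasonality peaking in mid-January (winter
heating + stagnant boundary layer) and bottoming in summer, and short-range
day-to-day persistence.  The generative form is

    value_t = max(floor, μ + A·cos(2π(doy_t − peak_day)/365.25) + e_t)

with AR(1) noise ``e_t = φ e_{t−1} + η_t`` scaled to a chosen stationary
standard deviation.  It is a deliberately simple surrogate: no weather
covariates, no heteroskedastic episodes, no multi-year trend.

``simulate_arma`` produces ARMA(p, q) sample paths with known coefficients
(optionally integrated ``d`` times) for parameter-recovery and
order-selection tests.  Coefficients use the same minus-sign MA convention
as the ARIMA forecaster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.arima_process import arma_generate_sample

from .series import DailySeries

__all__ = ["Pm25SimConfig", "simulate_pm25", "simulate_arma"]


@dataclass(frozen=True)
class Pm25SimConfig:
    """Settings of the seasonal AR(1) concentration generator.

    Defaults give an annual mean of 55 µg/m³ with a ±25 µg/m³ seasonal
    swing peaking around January 15, lag-1 noise autocorrelation 0.6 and
    stationary noise sd 12 µg/m³, truncated below at 1 µg/m³.
    """

    n_days: int
    annual_mean: float = 55.0
    seasonal_amplitude: float = 25.0
    peak_day: int = 15
    ar_coefficient: float = 0.6
    noise_sd: float = 12.0
    floor: float = 1.0
    seed: int = 0
    start: str = "2013-12-02"

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")


def simulate_pm25(config: Pm25SimConfig) -> DailySeries:
    """Generate a seeded PM2.5-like daily series (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, periods=config.n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_day) / 365.25
    )
    phi = config.ar_coefficient
    e = np.zeros(config.n_days)
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1 - phi**2)
        e[0] = rng.normal(0.0, config.noise_sd)  # stationary start
        eta = rng.normal(0.0, innov_sd, size=config.n_days)
        for t in range(1, config.n_days):
            e[t] = phi * e[t - 1] + eta[t]
    values = np.maximum(config.floor, config.annual_mean + seasonal + e)
    return DailySeries(dates, values)


def simulate_arma(
    n: int,
    phi: tuple[float, ...] = (),
    theta: tuple[float, ...] = (),
    d: int = 0,
    innovation_sd: float = 1.0,
    seed: int = 0,
    burn_in: int = 200,
) -> np.ndarray:
    """Sample an ARMA(p, q) path, integrated ``d`` times.

    ``phi`` and ``theta`` follow ``φ(B) x_t = θ(B) ε_t`` with both
    polynomials in the 1 − Σc·B^k form.  A non-stationary AR polynomial is
    warned about but not rejected (useful for stress tests).  The first
    ``burn_in`` draws are discarded so the retained path is effectively
    stationary before integration.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if d < 0:
        raise ValueError("d must be non-negative")
    ar = np.r_[1.0, -np.asarray(phi, dtype=float)]
    ma = np.r_[1.0, -np.asarray(theta, dtype=float)]
    if len(ar) > 1 and np.any(np.abs(np.roots(ar[::-1])) <= 1.0):
        warnings.warn("AR polynomial is not stationary", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    x = arma_generate_sample(
        ar, ma, nsample=n + burn_in, scale=innovation_sd, distrvs=rng.standard_normal
    )[burn_in:]
    for _ in range(d):
        x = np.cumsum(x)
    return x
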