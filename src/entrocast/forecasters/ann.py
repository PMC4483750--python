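"""Lagged feed-forward neural network forecaster.

A single-hidden-layer network maps a window of the ``L`` most recent values
to the next value: hyperbolic-tangent hidden units, one linear output unit.
Inputs and target are affinely normalized to [−1, 1] from the training
series' range before fitting (the customary scaling for tanh networks), and
forecasts are mapped back.  Training minimizes the mean squared error on the
normalized scale with L-BFGS from a seeded random initialization, stopping
at ``max_epochs`` iterations or as soon as the normalized training MSE
reaches ``target_mse``.  The same (series, config) pair therefore always
yields the same trained weights and the same forecasts.

Multi-step forecasts are iterated one-step predictions: each forecast is
appended to the input window for the next step.  Because the trained map is
typically a contraction on the normalized scale, iterated forecasts settle
toward its fixed point — long-horizon forecasts flatten to a near-constant
level close to the series mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ..series import DailySeries
from .base import ForecastResult

__all__ = ["AnnConfig", "LaggedNet", "AnnFit", "fit_ann", "forecast_ann"]


@dataclass(frozen=True)
class AnnConfig:
    """Network architecture and training settings.

    ``target_mse`` is on the normalized [−1, 1] training scale.
    """

    lag_window: int = 5
    hidden_units: int = 5
    max_epochs: int = 20_000
    target_mse: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_window < 1:
            raise ValueError("lag_window must be >= 1")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.target_mse <= 0:
            raise ValueError("target_mse must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class LaggedNet:
    """Trained network: weights plus the affine normalization it was fit under.

    The normalized forward map is ``tanh(z @ W1 + b1) @ w2 + b2``; the public
    ``predict`` works on the original µg/m³ scale.
    """

    W1: np.ndarray  # (lag_window, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    mid: float  # normalization centre: z = (x − mid)/half
    half: float  # normalization half-range; 1.0 for a degenerate constant series

    @property
    def lag_window(self) -> int:
        return self.W1.shape[0]

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mid) / self.half

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.half + self.mid

    def forward_normalized(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(Z)
        return np.tanh(Z @ self.W1 + self.b1) @ self.w2 + self.b2

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """One-step prediction for each row of lagged original-scale values."""
        W = np.atleast_2d(np.asarray(windows, dtype=float))
        return self.denormalize(self.forward_normalized(self.normalize(W)))


@dataclass(frozen=True)
class AnnFit:
    network: LaggedNet
    fitted: np.ndarray  # NaN for the first lag_window positions
    final_mse: float  # normalized-scale training MSE at the stopping point
    n_iter: int
    reached_target: bool
    config: AnnConfig


def _lag_matrix(z: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(z) - lag
    X = np.lib.stride_tricks.sliding_window_view(z, lag)[:n]
    return X, z[lag:]


def _pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _unpack(theta, lag, hidden):
    i = lag * hidden
    W1 = theta[:i].reshape(lag, hidden)
    b1 = theta[i : i + hidden]
    w2 = theta[i + hidden : i + 2 * hidden]
    b2 = theta[i + 2 * hidden]
    return W1, b1, w2, b2


def fit_ann(series: DailySeries | np.ndarray, config: AnnConfig = AnnConfig()) -> AnnFit:
    """Train the lagged network on (window → next value) pairs.

    Uses the exact normalized-MSE objective with its analytic gradient.
    Stops early once the objective falls to ``config.target_mse``.
    """
    x = series.values if isinstance(series, DailySeries) else np.asarray(series, dtype=float)
    L, H = config.lag_window, config.hidden_units
    if len(x) <= L + 1:
        raise ValueError(f"series of length {len(x)} too short for lag_window={L}")

    lo, hi = float(x.min()), float(x.max())
    mid = (hi + lo) / 2.0
    half = (hi - lo) / 2.0 or 1.0  # constant series: map everything to 0
    z = (x - mid) / half
    X, y = _lag_matrix(z, L)
    n = len(y)

    def loss_grad(theta):
        W1, b1, w2, b2 = _unpack(theta, L, H)
        A = np.tanh(X @ W1 + b1)  # (n, H)
        pred = A @ w2 + b2
        e = pred - y
        mse = float(np.mean(e**2))
        ce = (2.0 / n) * e
        gw2 = A.T @ ce
        gb2 = ce.sum()
        back = np.outer(ce, w2) * (1 - A**2)  # (n, H)
        gW1 = X.T @ back
        gb1 = back.sum(axis=0)
        return mse, _pack(gW1, gb1, gw2, gb2)

    rng = np.random.default_rng(config.seed)
    theta0 = rng.uniform(-0.5, 0.5, size=L * H + 2 * H + 1)

    def cb(intermediate_result):
        if intermediate_result.fun <= config.target_mse:
            raise StopIteration

    res = minimize(
        loss_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": config.max_epochs, "ftol": 1e-14, "gtol": 1e-12},
    )
    W1, b1, w2, b2 = _unpack(res.x, L, H)
    net = LaggedNet(W1=W1, b1=b1, w2=w2, b2=float(b2), mid=mid, half=half)
    final_mse = float(np.mean((net.forward_normalized(X) - y) ** 2))
    fitted = np.full(len(x), np.nan)
    fitted[L:] = net.denormalize(net.forward_normalized(X))
    return AnnFit(
        network=net,
        fitted=fitted,
        final_mse=final_mse,
        n_iter=int(res.nit),
        reached_target=final_mse <= config.target_mse,
        config=config,
    )


def forecast_ann(
    network: LaggedNet | AnnFit,
    history: DailySeries | np.ndarray,
    horizon: int,
) -> ForecastResult:
    """Iterated one-step forecasting from the end of ``history``.

    Each prediction is fed back (on the normalized scale) as the newest lag
    for the following step.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    fitted = np.empty(0)
    if isinstance(network, AnnFit):
        fitted = network.fitted
        network = network.network
    x = history.values if isinstance(history, DailySeries) else np.asarray(history, dtype=float)
    L = network.lag_window
    if len(x) < L:
        raise ValueError(f"history of length {len(x)} shorter than lag_window={L}")
    window = list(network.normalize(x[-L:]))
    out = np.empty(horizon)
    for h in range(horizon):
        z = float(network.forward_normalized(np.array(window))[0])
        out[h] = z
        window = window[1:] + [z]
    return ForecastResult(
        method="ann",
        fitted=fitted,
        forecasts=network.denormalize(out),
        params={"lag_window": L, "hidden_units": len(network.w2)},
    )
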