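"""End-to-end combination-forecast pipeline and the replay check.

``run_pipeline`` wires the stages together: split the series into a training
block and a holdout, fit the requested base forecasters on the training
block, derive entropy weights from their in-sample one-step predictions,
combine the out-of-sample forecasts, and score every forecast column
against the holdout with the six-index suite.  Weights are computed once on
the training window and held fixed over the whole horizon.

``replay`` is the opposite exercise: it takes published forecasts and
weights as fixed inputs and re-runs only the combination arithmetic and the
error indexes — no fitting, no random state — so the package's arithmetic
can be checked against published tables exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import BASES, EntropyWeights, combine as combine_forecasts, weights_from_history
from .fixtures import METHOD_COLUMNS, REFERENCE_WEIGHTS, load_guangzhou_jan2015
from .forecasters import (
    AnnConfig,
    fit_ann,
    fit_arima,
    fit_esm,
    forecast_ann,
    forecast_arima,
    forecast_esm,
    select_order,
)
from .metrics import MetricReport, evaluate_metrics
from .series import DailySeries, read_series
from .simulate import Pm25SimConfig, simulate_pm25

__all__ = ["RunConfig", "RunResult", "run_pipeline", "replay"]

logger = logging.getLogger("entrocast")

ALL_METHODS = ("arima", "ann", "esm")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings.

    Exactly one of ``input_path`` / ``simulate`` provides the series.
    ``holdout`` is the number of trailing days reserved for evaluation (10
    by default, matching the ten-day prediction design the reference table
    uses); ``extra_horizon`` extends the forecasts beyond the holdout.
    """

    input_path: str | None = None
    simulate: Pm25SimConfig | None = None
    holdout: int = 10
    extra_horizon: int = 0
    methods: tuple[str, ...] = ALL_METHODS
    basis: str = "accuracy_benefit"
    arima_order: tuple[int, int, int] | None = None
    max_p: int = 5
    max_q: int = 5
    ic: str = "bic"
    alpha: float = 0.15
    lag_window: int = 5
    hidden_units: int = 5
    max_epochs: int = 20_000
    target_mse: float = 0.001
    seed: int = 0
    output_dir: str | None = None
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input_path or simulate")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.holdout < 1 or self.extra_horizon < 0:
            raise ValueError("holdout must be >= 1 and extra_horizon >= 0")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")  # where artifacts land must not change their content
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class RunResult:
    train: DailySeries
    test: DailySeries
    forecasts: pd.DataFrame  # step, date, one column per method, cfm
    weights: EntropyWeights
    metrics: dict[str, MetricReport]  # per forecast column, over the holdout
    params: dict[str, dict]
    config_hash: str
    seed: int


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full pipeline; see module docstring for the stages."""
    with _stage("load"):
        if config.input_path is not None:
            series = read_series(config.input_path, allow_gaps=config.allow_gaps)
        else:
            series = simulate_pm25(config.simulate)

    with _stage("split"):
        from .series import split_holdout

        train, test = split_holdout(series, config.holdout)
    n_steps = config.holdout + config.extra_horizon

    fitted_rows: list[np.ndarray] = []
    forecast_rows: list[np.ndarray] = []
    params: dict[str, dict] = {}
    for method in config.methods:
        with _stage(f"fit:{method}"):
            if method == "arima":
                order = config.arima_order or select_order(
                    train, max_p=config.max_p, max_q=config.max_q, ic=config.ic
                )
                fit = fit_arima(train, order)
                result = forecast_arima(fit, horizon=n_steps)
                logger.info(
                    "arima order=%s ljung_box_p=%.4f", order, fit.ljung_box_pvalue
                )
            elif method == "ann":
                cfg = AnnConfig(
                    lag_window=config.lag_window,
                    hidden_units=config.hidden_units,
                    max_epochs=config.max_epochs,
                    target_mse=config.target_mse,
                    seed=config.seed,
                )
                fit = fit_ann(train, cfg)
                result = forecast_ann(fit, train, n_steps)
                result.params.update(
                    n_iter=fit.n_iter,
                    final_mse=fit.final_mse,
                    reached_target=fit.reached_target,
                )
                logger.info(
                    "ann n_iter=%d final_mse=%.6f", fit.n_iter, fit.final_mse
                )
            else:
                fit = fit_esm(train, alpha=config.alpha)
                result = forecast_esm(fit, n_steps)
                logger.info("esm alpha=%.3f init=%.3f", config.alpha, fit.init_value)
            fitted_rows.append(result.fitted)
            forecast_rows.append(result.forecasts)
            params[method] = dict(result.params)

    with _stage("weights"):
        fitted = np.vstack(fitted_rows)
        valid = np.all(np.isfinite(fitted), axis=0)
        if valid.sum() < 2:
            raise ValueError("fewer than 2 jointly fitted training points")
        weights = weights_from_history(
            train.values[valid], fitted[:, valid], basis=config.basis
        )
        logger.info(
            "weights %s basis=%s",
            dict(zip(config.methods, np.round(weights.weights, 4))),
            config.basis,
        )

    with _stage("combine"):
        F = np.vstack(forecast_rows)
        cfm = combine_forecasts(F, weights.weights)

    with _stage("evaluate"):
        metrics = {
            name: evaluate_metrics(test.values, row[: config.holdout])
            for name, row in zip(config.methods, forecast_rows)
        }
        metrics["cfm"] = evaluate_metrics(test.values, cfm[: config.holdout])

    dates = pd.date_range(
        train.dates[-1] + pd.Timedelta(days=1), periods=n_steps, freq="D"
    )
    forecasts = pd.DataFrame({"step": np.arange(1, n_steps + 1), "date": dates})
    for name, row in zip(config.methods, forecast_rows):
        forecasts[name] = row
    forecasts["cfm"] = cfm

    result = RunResult(
        train=train,
        test=test,
        forecasts=forecasts,
        weights=weights,
        metrics=metrics,
        params=params,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if config.output_dir is not None:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config_hash, "seed": result.seed}
    df = result.forecasts.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(out / "forecasts.csv", index=False, float_format="%.10g")
    (out / "weights.json").write_text(
        json.dumps(
            {
                **stamp,
                "basis": result.weights.basis,
                "methods": list(config.methods),
                "weights": result.weights.weights.tolist(),
                "entropies": result.weights.entropies.tolist(),
                "degenerate_rows": list(result.weights.degenerate_rows),
            },
            indent=2,
        )
    )
    (out / "metrics.json").write_text(
        json.dumps(
            {**stamp, "metrics": {k: v.to_dict() for k, v in result.metrics.items()}},
            indent=2,
        )
    )
    (out / "params.json").write_text(
        json.dumps({**stamp, "params": result.params}, indent=2, default=str)
    )


def replay(
    table: pd.DataFrame | None = None,
    weights: np.ndarray | None = None,
    method_columns: tuple[str, ...] = METHOD_COLUMNS,
) -> dict:
    """Recompute the combination and error indexes from published values.

    Uses the packaged Guangzhou ten-day table and its published weight
    triple by default.  Touches no random state and no fitting code.

    Returns a dict with the recomputed combined column (``combined``), the
    published one if present (``published_combined``), and a
    :class:`MetricReport` per forecast column (``metrics``).
    """
    if table is None:
        table = load_guangzhou_jan2015()
    if weights is None:
        weights = REFERENCE_WEIGHTS
    F = np.vstack([table[c].to_numpy(dtype=float) for c in method_columns])
    combined = combine_forecasts(F, weights)
    actual = table["actual"].to_numpy(dtype=float)
    metrics = {c: evaluate_metrics(actual, table[c].to_numpy(dtype=float)) for c in method_columns}
    metrics["cfm"] = evaluate_metrics(actual, combined)
    out = {
        "combined": combined,
        "metrics": metrics,
        "weights": np.asarray(weights, dtype=float),
    }
    if "cfm" in table.columns:
        out["published_combined"] = table["cfm"].to_numpy(dtype=float)
    return out
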