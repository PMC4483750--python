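"""Fit the three base forecasters on one series and compare their styles.

ARIMA tracks the stochastic short-range structure, the lagged network
settles toward the level it learned (iterated forecasts of a contraction
flatten), and Brown quadratic smoothing extrapolates a local quadratic
trend — so the three disagree in characteristic ways.
"""

import numpy as np

import entrocast as ec

series = ec.simulate_pm25(ec.Pm25SimConfig(n_days=420, seed=7))
train, test = ec.split_holdout(series, 10)

order = ec.select_order(train, max_p=3, max_q=3)
arima = ec.forecast_arima(ec.fit_arima(train, order), horizon=10)
ann = ec.forecast_ann(ec.fit_ann(train, ec.AnnConfig(seed=7)), train, 10)
esm = ec.forecast_esm(ec.fit_esm(train, alpha=0.15), 10)

print(f"selected ARIMA order: {order}")
print(f"\n{'day':>4} {'actual':>8} {'arima':>8} {'ann':>8} {'esm':>8}")
for i in range(10):
    print(f"{i + 1:>4} {test.values[i]:8.2f} {arima.forecasts[i]:8.2f} "
          f"{ann.forecasts[i]:8.2f} {esm.forecasts[i]:8.2f}")
for name, r in (("arima", arima), ("ann", ann), ("esm", esm)):
    mae = np.mean(np.abs(test.values - r.forecasts))
    print(f"{name:>6} 10-day MAE: {mae:6.2f} ug/m3")
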