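"""Replay the packaged ten-day Guangzhou reference comparison.

The package ships a published ten-day table of actual PM2.5 values for
Guangzhou (22-31 Jan 2015) with forecasts from an ARIMA model, a neural
network, exponential smoothing, and their entropy-weighted combination
(weight triple 0.2399 / 0.5419 / 0.2182).  Replay re-runs only the
combination arithmetic and the error indexes from those fixed inputs — no
fitting, no randomness — and the recomputed numbers match the published
ones to four decimals.
"""

import entrocast as ec

out = ec.replay()

print("recomputed vs published combined forecast (ug/m3):")
for i, (got, pub) in enumerate(zip(out["combined"], out["published_combined"]), 1):
    print(f"  day {i:>2}: {got:9.4f}  vs  {pub:9.4f}")

print("\nsix error indexes per forecast column:")
for name, r in out["metrics"].items():
    print(f"  {name:>6}: MAE {r.mae:7.4f}  MPE {r.mpe:6.4f}  RMSE {r.rmse:7.4f}  "
          f"U {r.theil_u:6.4f}  BR {r.bias_ratio:6.4f}  VR {r.variance_ratio:6.4f}")
print("\nthe combination has the lowest MAE, MPE, RMSE and Theil U of the four")
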