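"""Generate a PM2.5-like daily series and inspect its seasonal structure.

The generator produces a positive daily concentration series with a winter
peak, a summer trough, and day-to-day persistence — the gross features of
urban fine-particulate records from southern coastal China.
"""

import entrocast as ec

config = ec.Pm25SimConfig(n_days=420, seed=7, start="2013-12-02")
series = ec.simulate_pm25(config)

print(f"{len(series)} days from {series.dates[0].date()} to {series.dates[-1].date()}")
print(f"mean {series.values.mean():.1f} ug/m3, min {series.values.min():.1f}, "
      f"max {series.values.max():.1f}")
print("\nmonthly means (winter high, summer low):")
for m in ec.monthly_means(series):
    print(f"  {m.year}-{m.month:02d}: {m.mean_value:6.1f} ug/m3  ({m.n_days} days)")
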