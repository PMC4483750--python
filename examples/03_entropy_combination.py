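"""Weight the three forecasters by entropy and combine their forecasts.

Each method's in-sample relative-accuracy profile is min-max normalized and
scored by Shannon entropy: a method whose profile is more dispersed (lower
entropy) is more informative and earns a larger convex weight.  The
combined forecast is the weighted sum, step by step, and always lies
between the lowest and highest member forecast.
"""

import entrocast as ec

config = ec.RunConfig(
    simulate=ec.Pm25SimConfig(n_days=420, seed=7),
    holdout=10,
    seed=7,
    max_p=3,
    max_q=3,
)
result = ec.run_pipeline(config)

for name, p, w in zip(config.methods, result.weights.entropies, result.weights.weights):
    print(f"{name:>6}: entropy p = {p:.4f}  ->  weight = {w:.4f}")
print(f"weights sum to {result.weights.weights.sum():.6f} (basis: {result.weights.basis})")

print(f"\n{'day':>4} {'arima':>8} {'ann':>8} {'esm':>8} {'combined':>9}")
for _, row in result.forecasts.iterrows():
    print(f"{int(row['step']):>4} {row['arima']:8.2f} {row['ann']:8.2f} "
          f"{row['esm']:8.2f} {row['cfm']:9.2f}")
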