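"""Score holdout forecasts with the six-index error suite.

MAE and RMSE are absolute errors in ug/m3; MPE is the mean absolute
relative error; the Theil coefficient is a scale-free error index (here
with relative errors in its numerator); the bias and variance ratios
compare the squared mean gap and squared spread gap to the mean squared
error.  All six are zero for a perfect forecast and smaller is better.
"""

import entrocast as ec

result = ec.run_pipeline(
    ec.RunConfig(
        simulate=ec.Pm25SimConfig(n_days=420, seed=7),
        holdout=10,
        seed=7,
        max_p=3,
        max_q=3,
    )
)

header = f"{'index':>15}" + "".join(f"{m:>10}" for m in result.metrics)
print(header)
for key in ("mae", "mpe", "rmse", "theil_u", "bias_ratio", "variance_ratio"):
    row = f"{key:>15}"
    for report in result.metrics.values():
        row += f"{getattr(report, key):10.4f}"
    print(row)
print("\nlower is better on every row; the combination trades a little "
      "best-case accuracy for robustness across days")
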