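"""Statistical comparison of estimation strategies.

Builds a small tidy results table (reference vs a biased alternative
strategy across conditions), computes per-condition RMSEs, and runs
the normality-gated one-way and two-way comparisons.
"""
import numpy as np
import pandas as pd

from stridevar.stats import evaluate_strategies

rng = np.random.default_rng(0)
rows = []
cond_means = {"-8%": 0.56, "level": 0.72, "+8%": 0.76}
for runner in [f"R{i:02d}" for i in range(12)]:
    offset = rng.normal(0, 0.03)
    for cond, mu in cond_means.items():
        ref = mu + offset + rng.normal(0, 0.04)
        rows.append(dict(runner=runner, condition=cond, variable="DFA",
                         strategy="reference", unit=-1, value=ref))
        # alternative strategy: biased upward, extra noise
        rows.append(dict(runner=runner, condition=cond, variable="DFA",
                         strategy="imu_alt", unit=-1, value=ref + 0.06 + rng.normal(0, 0.05)))

table = pd.DataFrame(rows)
result = evaluate_strategies(table, reference="reference")

print("per-condition RMSE of the alternative strategy vs reference:")
print(result.rmse_rows.to_string(index=False))

ow = result.one_way["DFA"]
print(f"\none-way across conditions ({ow.branch}): {ow.test_name} "
      f"stat={ow.statistic:.2f}, p={ow.p_value:.2g}, {ow.effect_name}={ow.effect_size:.3f}")
if ow.posthoc is not None:
    print(ow.posthoc.to_string(index=False))

tw = result.two_way["DFA"]
print(f"\ntwo-way condition x strategy ({tw.branch} branch primary):")
print(tw.primary["PR(>F)"].rename("p").to_string())
print("\nthe strategy main effect reflects the built-in +0.06 bias;")
print("the condition effect reflects the downhill-to-uphill spread.")
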