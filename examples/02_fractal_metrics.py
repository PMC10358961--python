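"""Fractal variability indices of stride-interval series.

Generates stride series with three prescribed correlation regimes and
reads their structure back with the package's DFA and Higuchi
estimators. DFA-alpha near 0.5 indicates an uncorrelated (white)
stride pattern, near 1.0 a 1/f (pink) pattern, and intermediate
values mixed structure; Higuchi's D moves oppositely (2 for white,
lower for correlated series).
"""
import numpy as np

from stridevar import RunnerSpec, generate_stride_series, variability_from_stride_frequency

print(f"{'regime':>12s} {'hurst':>6s} {'DFA-alpha':>10s} {'Higuchi-D':>10s}")
for label, hurst in [("white", 0.5), ("mixed", 0.75), ("pink (1/f)", 1.0)]:
    alphas, ds = [], []
    for seed in range(10):
        spec = RunnerSpec(runner_id="demo", hurst=hurst, seed=seed)
        series = generate_stride_series(840, spec)
        v = variability_from_stride_frequency(series.stride_frequencies)
        alphas.append(v.dfa_alpha)
        ds.append(v.higuchi_d)
    print(f"{label:>12s} {hurst:6.2f} {np.mean(alphas):10.3f} {np.mean(ds):10.3f}")

print("\nmean DFA-alpha tracks the generating Hurst exponent;")
print("Higuchi-D is ~2 for white stride series and falls as correlation grows.")
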