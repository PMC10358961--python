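"""Simulate a runner cohort and write one trial to delimited text.

Builds a two-runner cohort for a single 2-minute level condition,
realizes the thorax and foot recordings for the first trial, and
writes them (plus the ground-truth gait events) as CSV files.
"""
from pathlib import Path

from stridevar import ConditionSpec, generate_cohort
from stridevar.io import write_events, write_recording

out = Path("example_output")
out.mkdir(exist_ok=True)

cohort = generate_cohort(
    n_runners=2,
    conditions=[ConditionSpec(speed_pct_prs=100, duration=120.0)],
    master_seed=7,
)
trial = cohort.trials[0]
data = cohort.realize(trial)

print(f"runner {trial.runner_id}, condition {trial.condition.label}")
print(f"  generating stride frequency: {trial.spec.mean_stride_frequency:.3f} Hz")
print(f"  generating duty factor:      {trial.spec.mean_duty_factor:.3f}")
print(f"  generating Hurst exponent:   {trial.spec.hurst:.3f}")
print(f"  thorax recording: {data.thorax.n_samples} samples at {data.thorax.sampling_rate:.0f} Hz")

meta = {"runner": trial.runner_id, "condition": trial.condition.label, "seed": trial.spec.seed}
write_recording(data.thorax, out / "thorax.csv", metadata=meta)
write_recording(data.left_foot, out / "left_foot.csv", metadata=meta)
write_recording(data.right_foot, out / "right_foot.csv", metadata=meta)
write_events([data.left_events, data.right_events], out / "events.csv")
print(f"wrote recordings and events under {out}/")
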