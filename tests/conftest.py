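import pytest

from stridevar.types import RunnerSpec
from stridevar.synthetic import generate_stride_pair, generate_stride_series, synthesize_foot_imu


@pytest.fixture(scope="session")
def runner_spec():
    return RunnerSpec(runner_id="r0", seed=42)


@pytest.fixture(scope="session")
def quiet_spec():
    return RunnerSpec(runner_id="r0", seed=42, noise_amplitude=0.0)


@pytest.fixture(scope="session")
def foot_trial(runner_spec):
    """200-stride foot recording with ground truth, default noise."""
    strides = generate_stride_series(200, runner_spec)
    rec, events = synthesize_foot_imu(strides, runner_spec)
    return strides, rec, events


@pytest.fixture(scope="session")
def stride_pair(runner_spec):
    return generate_stride_pair(300, runner_spec)
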