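"""Synthetic cohort generator: determinism, event consistency, signal geometry."""
import numpy as np
import pytest

from stridevar.events import acceleration_norm, detect_strides
from stridevar.fractal import dfa_alpha
from stridevar.synthetic import (
    CONDITION_MEANS,
    generate_cohort,
    generate_stride_pair,
    generate_stride_series,
    split_by_runner,
    synthesize_foot_imu,
    synthesize_thorax_imu,
)
from stridevar.types import ConditionSpec, DegenerateInputError, RunnerSpec, StrideSeries


class TestStrideSeries:
    def test_seeded_determinism_bit_identical(self, runner_spec):
        a = generate_stride_series(128, runner_spec)
        b = generate_stride_series(128, runner_spec)
        np.testing.assert_array_equal(a.intervals, b.intervals)
        np.testing.assert_array_equal(a.contact_times, b.contact_times)

    def test_mean_cv_and_hurst_are_honoured(self):
        spec = RunnerSpec(runner_id="x", mean_stride_frequency=1.40, stride_cv=0.02,
                          hurst=0.75, seed=5)
        alphas, means, cvs = [], [], []
        for s in range(25):
            sp = RunnerSpec(runner_id="x", mean_stride_frequency=1.40, stride_cv=0.02,
                            hurst=0.75, seed=s)
            ser = generate_stride_series(840, sp)
            means.append(ser.intervals.mean())
            cvs.append(ser.intervals.std() / ser.intervals.mean())
            alphas.append(dfa_alpha(ser).dfa_alpha)
        assert np.mean(means) == pytest.approx(1 / 1.40, rel=0.01)
        assert np.mean(cvs) == pytest.approx(0.02, rel=0.15)
        assert np.mean(alphas) == pytest.approx(0.75, abs=0.05)

    def test_zero_cv_constant_series_refused_downstream(self):
        spec = RunnerSpec(runner_id="x", stride_cv=0.0, seed=1)
        ser = generate_stride_series(128, spec)
        assert np.ptp(ser.intervals) == 0
        with pytest.raises(DegenerateInputError):
            dfa_alpha(ser)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_stride_series(32, RunnerSpec(runner_id="x", seed=0))
        with pytest.raises(ValueError):
            generate_stride_series(128, RunnerSpec(runner_id="x", stride_cv=0.6, seed=0))

    def test_event_series_reconstruction_is_exact(self, runner_spec):
        """Strides -> events -> strides is lossless."""
        ser = generate_stride_series(128, runner_spec)
        back = StrideSeries.from_events(ser.to_events())
        np.testing.assert_allclose(back.intervals, ser.intervals, rtol=0, atol=1e-12)
        np.testing.assert_allclose(back.contact_times, ser.contact_times, rtol=0, atol=1e-12)


class TestFootIMU:
    def test_noiseless_detection_within_one_sample(self, quiet_spec):
        strides = generate_stride_series(150, quiet_spec)
        rec, events = synthesize_foot_imu(strides, quiet_spec)
        det = detect_strides(acceleration_norm(rec), rec.sampling_rate)
        for t in det.foot_strikes:
            assert np.min(np.abs(events.foot_strikes - t)) <= 1.0 / rec.sampling_rate
        # every interior truth strike is recovered
        interior = events.foot_strikes[
            (events.foot_strikes > 1) & (events.foot_strikes < rec.duration - 1)
        ]
        for t in interior:
            assert np.min(np.abs(det.foot_strikes - t)) <= 1.0 / rec.sampling_rate

    def test_duration_times_rate_sets_length(self, quiet_spec):
        strides = generate_stride_series(840, quiet_spec)
        rec, _ = synthesize_foot_imu(strides, quiet_spec, fs=208.0, duration=600.0)
        assert rec.n_samples == 124_800
        assert all(len(c) == 124_800 for c in rec.channels())

    def test_detected_sf_close_to_generating_mean(self, foot_trial):
        strides, rec, _ = foot_trial
        det = detect_strides(acceleration_norm(rec), rec.sampling_rate)
        sf_det = 1.0 / np.diff(det.foot_strikes).mean()
        sf_true = strides.stride_frequencies.mean()
        assert abs(sf_det - sf_true) / sf_true < 0.005


class TestThoraxIMU:
    def test_spectral_peak_at_step_frequency(self, stride_pair, runner_spec):
        left, right = stride_pair
        rec = synthesize_thorax_imu(left, right, runner_spec)
        az = rec.acc[2] - rec.acc[2].mean()
        f = np.fft.rfftfreq(len(az), 1 / rec.sampling_rate)
        p = np.abs(np.fft.rfft(az)) ** 2
        band = (f > 0.3) & (f < 5.0)
        peak = f[band][np.argmax(p[band])]
        step_freq = 2.0 * left.stride_frequencies.mean()
        assert peak == pytest.approx(step_freq, rel=0.02)

    def test_deterministic_under_seed(self, stride_pair, runner_spec):
        left, right = stride_pair
        a = synthesize_thorax_imu(left, right, runner_spec)
        b = synthesize_thorax_imu(left, right, runner_spec)
        np.testing.assert_array_equal(a.channels(), b.channels())

    def test_non_interleaved_feet_rejected(self, runner_spec):
        left = generate_stride_series(80, runner_spec, foot="left")
        # a shifted copy of the left series cannot alternate with it
        far_right = StrideSeries(
            foot="right",
            start_times=left.start_times + 2.5 * left.intervals,
            intervals=left.intervals,
            contact_times=left.contact_times,
        )
        with pytest.raises(ValueError, match="interleave"):
            synthesize_thorax_imu(left, far_right, runner_spec)

    def test_mediolateral_channel_alternates_sign_with_foot(self, stride_pair, runner_spec):
        left, right = stride_pair
        spec = RunnerSpec(**{**runner_spec.__dict__, "noise_amplitude": 0.0})
        rec = synthesize_thorax_imu(left, right, spec)
        fs = rec.sampling_rate
        mid_l = (left.start_times[:50] + left.contact_times[:50] / 2 * 1.0)
        mid_r = (right.start_times[:50] + right.contact_times[:50] / 2 * 1.0)
        assert np.all(rec.acc[0][(mid_l * fs).astype(int)] > 0)
        assert np.all(rec.acc[0][(mid_r * fs).astype(int)] < 0)


class TestCohort:
    def test_full_protocol_trial_count(self):
        ds = generate_cohort(20, master_seed=9)
        assert len(ds.trials) == 20 * 11

    def test_duty_factor_means_fall_with_speed(self):
        dfs = [CONDITION_MEANS[f"{s}%PRS"][1] for s in (80, 90, 100, 110, 120)]
        assert np.all(np.diff(dfs) < 0)
        assert dfs[0] == pytest.approx(0.448, abs=0.005)
        assert dfs[-1] == pytest.approx(0.366, abs=0.005)

    def test_inclination_perturbs_hurst_monotonically(self):
        hs = [CONDITION_MEANS[k][2] for k in ("-8%", "-5%", "-2%", "+2%", "+5%", "+8%")]
        assert np.all(np.diff(hs) > 0)

    def test_split_by_runner_is_a_partition(self):
        ds = generate_cohort(20, master_seed=9)
        train, test = split_by_runner(ds, seed=1)
        assert len(train) == len(test) == 10
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(ds.runner_ids)

    def test_realized_trial_is_consistent(self):
        conds = [ConditionSpec(speed_pct_prs=100, duration=60.0)]
        ds = generate_cohort(2, conds, master_seed=4)
        td = ds.realize(ds.trials[0])
        assert td.thorax.n_samples == int(60.0 * 208)
        # ground-truth events reconstruct the generating stride series exactly
        back = StrideSeries.from_events(td.left_events)
        np.testing.assert_allclose(back.intervals, td.left_strides.intervals, atol=1e-12)
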