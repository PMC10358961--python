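"""Short- and long-window estimators: windowing, training, prediction."""
import numpy as np
import pytest

from stridevar.estimators import (
    dfa_from_short_path,
    make_short_windows,
    normalize_short_input,
    predict_long,
    predict_short,
    train_long,
    train_short,
)
from stridevar.events import temporal_variables, windowed_average
from stridevar.synthetic import generate_cohort
from stridevar.types import ConditionSpec


@pytest.fixture(scope="module")
def micro_cohort():
    """Four runners, one 240-s level condition: enough for training smoke."""
    conds = [ConditionSpec(speed_pct_prs=90, duration=240.0)]
    cohort = generate_cohort(4, conds, master_seed=11)
    out = {}
    for trial in cohort.trials:
        td = cohort.realize(trial)
        tv_l = temporal_variables(td.left_events)
        tv_r = temporal_variables(td.right_events)
        wins = windowed_average(tv_l, tv_r, 240.0)
        x, y, valid = make_short_windows(td.thorax, wins)
        out[trial.runner_id] = (x[valid], y[valid], td)
    return out


class TestMakeShortWindows:
    def test_window_count_and_shape(self, micro_cohort):
        x, y, _ = next(iter(micro_cohort.values()))
        assert x.shape[1:] == (6, 416)
        assert y.shape[1] == 4
        assert len(x) <= 239  # (240 - 2)/1 + 1

    def test_gravity_normalisation_constant(self):
        acc = np.full((3, 416), 9.81)
        gyro = np.full((3, 416), 500.0)
        x = normalize_short_input(acc, gyro)
        np.testing.assert_allclose(x[:3], 1.0)
        np.testing.assert_allclose(x[3:], 1.0)

    def test_label_standardisation_roundtrip(self, short_model):
        y = np.array([[1.4, 1.38, 0.4, 0.41]])
        z = short_model.standardize_labels(y)
        np.testing.assert_allclose(short_model.destandardize_labels(z), y, atol=1e-12)


@pytest.fixture(scope="module")
def short_model(micro_cohort):
    samples = {r: (x, y) for r, (x, y, _) in micro_cohort.items()}
    return train_short(samples, train_runners=["R00", "R01"], seed=0, epochs=2)


class TestShortModel:
    def test_split_hygiene(self, micro_cohort):
        samples = {r: (x, y) for r, (x, y, _) in micro_cohort.items()}
        with pytest.raises(ValueError):
            train_short(samples, train_runners=["R00", "nope"], seed=0, epochs=1)
        with pytest.raises(ValueError):
            train_short(samples, train_runners=["R00"], seed=0, epochs=1)

    def test_training_is_deterministic(self, micro_cohort):
        samples = {r: (x, y) for r, (x, y, _) in micro_cohort.items()}
        a = train_short(samples, ["R00", "R01"], seed=3, epochs=2)
        b = train_short(samples, ["R00", "R01"], seed=3, epochs=2)
        x = micro_cohort["R02"][0][:8]
        pa = [w.as_vector() for w in predict_short(a, x)]
        pb = [w.as_vector() for w in predict_short(b, x)]
        np.testing.assert_array_equal(pa, pb)

    def test_predict_clips_and_is_finite(self, short_model):
        outs = predict_short(short_model, np.zeros((3, 6, 416)))
        for w in outs:
            v = w.as_vector()
            assert np.all(np.isfinite(v))
            assert 0.5 <= v[0] <= 3.0 and 0.0 < v[2] < 1.0

    def test_single_equals_batch(self, short_model, micro_cohort):
        x = micro_cohort["R02"][0][:5]
        batch = [w.as_vector() for w in predict_short(short_model, x)]
        singles = [predict_short(short_model, xi)[0].as_vector() for xi in x]
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_repeat_prediction_identical(self, short_model, micro_cohort):
        x = micro_cohort["R02"][0][:5]
        a = [w.as_vector() for w in predict_short(short_model, x)]
        b = [w.as_vector() for w in predict_short(short_model, x)]
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_rejected(self, short_model):
        with pytest.raises(ValueError):
            predict_short(short_model, np.zeros((6, 400)))


class TestLongModel:
    @pytest.fixture(scope="class")
    def long_setup(self):
        rng = np.random.default_rng(0)
        samples = {}
        for r in range(4):
            x = rng.standard_normal((120, 6, 23))
            y = 0.6 + 0.3 * x[:, 2, 9] + 0.02 * rng.standard_normal(120)
            samples[f"R{r:02d}"] = (x, y)
        return samples

    def test_learns_better_than_mean_baseline(self, long_setup):
        est = train_long(long_setup, ["R00", "R01", "R02"], seed=0, epochs=300)
        x_te, y_te = long_setup["R03"]
        pred = predict_long(est, x_te)
        rmse_model = np.sqrt(np.mean((pred - y_te) ** 2))
        y_tr = np.concatenate([long_setup[r][1] for r in ("R00", "R01", "R02")])
        rmse_base = np.sqrt(np.mean((y_tr.mean() - y_te) ** 2))
        assert rmse_model < rmse_base

    def test_dropout_off_at_prediction(self, long_setup):
        est = train_long(long_setup, ["R00", "R01"], seed=1, epochs=5)
        x = long_setup["R03"][0][:4]
        np.testing.assert_array_equal(predict_long(est, x), predict_long(est, x))

    def test_feature_standardisation_stored(self, long_setup):
        est = train_long(long_setup, ["R00", "R01"], seed=1, epochs=2)
        assert est.feature_mean.shape == (138,)
        assert np.all(est.feature_sd > 0)


class TestShortPathComposition:
    def test_equals_manual_composition(self, short_model, micro_cohort):
        from stridevar.estimators import GYRO_NORM, SHORT_STEP_S, SHORT_WINDOW_S
        from stridevar.events import window_grid
        from stridevar.fractal import variability_from_stride_frequency

        td = micro_cohort["R02"][2]
        res = dfa_from_short_path(short_model, td.thorax)
        starts = window_grid(td.thorax.duration, SHORT_WINDOW_S, SHORT_STEP_S)
        fs = td.thorax.sampling_rate
        chans = td.thorax.channels().copy()
        chans[3:] /= GYRO_NORM
        xs = np.array(
            [chans[:, int(round(t * fs)) : int(round(t * fs)) + 416] for t in starts]
        )
        preds = predict_short(short_model, xs)
        sf = np.array([(p.sf_left + p.sf_right) / 2 for p in preds])
        manual = variability_from_stride_frequency(sf)
        assert res.dfa_alpha == pytest.approx(manual.dfa_alpha, abs=1e-12)
        assert res.higuchi_d == pytest.approx(manual.higuchi_d, abs=1e-12)

    def test_constant_predictions_degenerate(self, short_model):
        from stridevar.types import DegenerateInputError, IMURecording

        flat = IMURecording(
            placement="thorax",
            sampling_rate=208.0,
            acc=np.zeros((3, 208 * 90)),
            gyro=np.zeros((3, 208 * 90)),
        )
        with pytest.raises(DegenerateInputError):
            dfa_from_short_path(short_model, flat)


def test_estimator_bundle_roundtrip(tmp_path, short_model, micro_cohort):
    """A saved model bundle reloads to bit-identical predictions."""
    from stridevar.estimators import load_estimator, save_estimator

    save_estimator(short_model, tmp_path / "bundle")
    back = load_estimator(tmp_path / "bundle")
    x = micro_cohort["R02"][0][:4]
    a = [w.as_vector() for w in predict_short(short_model, x)]
    b = [w.as_vector() for w in predict_short(back, x)]
    np.testing.assert_allclose(a, b, atol=1e-12)
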