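"""Thorax-IMU machine-learning estimators.

Two regression strategies share one thorax sensor:

* the **short-window model**: a small 1-D convolutional network mapping
  a 2-s, 6 x 416 normalized inertial window to the 4-vector
  (sf_left, sf_right, df_left, df_right), trained against reference
  window averages with labels z-standardized on the training split;
* the **long-window model**: a dense 128-64-32-1 network with batch
  normalisation and dropout mapping the 6 x 23 feature matrix of a
  120-s window to a single DFA-alpha (the left/right average of the
  reference), one label per condition shared by its windows.

Splits are always by runner, never by window. Composing the short
model's stride-frequency predictions with the fractal metrics gives
the short-path DFA-alpha, the baseline the long model is compared to.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .events import window_grid
from .fractal import variability_from_stride_frequency
from .features import FeatureMatrix
from .types import IMURecording, VariabilityIndices, WindowEstimate

__all__ = [
    "save_estimator",
    "load_estimator",
    "GYRO_NORM",
    "ACC_NORM",
    "normalize_short_input",
    "make_short_windows",
    "train_short",
    "predict_short",
    "train_long",
    "predict_long",
    "dfa_from_short_path",
    "TrainedEstimator",
]

#: acceleration normalizer, m/s^2 per g
ACC_NORM = 9.81
#: angular-velocity normalizer, sensor units (kept verbatim from the
#: recording convention even though the unit is dimensionally odd)
GYRO_NORM = 500.0
SHORT_WINDOW_S = 2.0
SHORT_STEP_S = 1.0
SF_CLIP = (0.5, 3.0)
DF_CLIP = (1e-3, 1.0 - 1e-3)


def normalize_short_input(acc_ms2: np.ndarray, gyro: np.ndarray) -> np.ndarray:
    """Stack a raw window into the normalized 6 x L model input.

    Accelerations arrive in m/s^2 and are divided by 9.81; angular
    velocities are divided by the 500-unit gyro normalizer.
    """
    return np.vstack([np.asarray(acc_ms2) / ACC_NORM, np.asarray(gyro) / GYRO_NORM])


@dataclass
class TrainedEstimator:
    """A trained model plus everything needed to reproduce predictions."""

    kind: str  # "short" | "long"
    model: nn.Sequential
    architecture: str
    label_mean: np.ndarray
    label_sd: np.ndarray
    feature_mean: Optional[np.ndarray] = None
    feature_sd: Optional[np.ndarray] = None
    train_runners: Tuple[str, ...] = ()
    seed: int = 0
    n_clipped: int = 0

    def standardize_labels(self, y: np.ndarray) -> np.ndarray:
        return (y - self.label_mean) / self.label_sd

    def destandardize_labels(self, z: np.ndarray) -> np.ndarray:
        return z * self.label_sd + self.label_mean


def make_short_windows(
    thorax: IMURecording,
    reference: Sequence[WindowEstimate],
    step: float = SHORT_STEP_S,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-second 2-s input windows aligned with reference labels.

    Returns (X, y, valid): X has shape (n, 6, 416) with the gyro
    channels divided by the 500-unit normalizer (accelerations are
    already in g), y the 4-vectors from the reference grid, and
    ``valid`` flags windows whose reference carries all four values.
    Windows with missing reference must be excluded from training.
    """
    fs = thorax.sampling_rate
    n_samp = int(round(SHORT_WINDOW_S * fs))
    chans = thorax.channels().copy()
    chans[3:] /= GYRO_NORM
    xs, ys, valid = [], [], []
    for w in reference:
        if abs((w.window_start - thorax.start_time) * fs - round((w.window_start - thorax.start_time) * fs)) > 1:
            raise ValueError("reference grid and thorax clock differ by more than one sample")
        i0 = int(round((w.window_start - thorax.start_time) * fs))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > thorax.n_samples:
            continue
        xs.append(chans[:, i0:i1])
        ys.append(w.as_vector())
        valid.append(w.valid)
    return np.array(xs), np.array(ys), np.array(valid, dtype=bool)


def _short_architecture(rng: np.random.Generator) -> Tuple[nn.Sequential, str]:
    layers = [
        nn.Conv1D(6, 12, 15, rng),
        nn.ReLU(),
        nn.MaxPool1D(4),
        nn.Conv1D(12, 24, 9, rng),
        nn.ReLU(),
        nn.MaxPool1D(4),
        nn.Flatten(),
        nn.Dense(24 * 23, 64, rng),
        nn.ReLU(),
        nn.Dense(64, 4, rng),
    ]
    desc = "conv(6->12,k15)-pool4-conv(12->24,k9)-pool4-dense64-dense4"
    return nn.Sequential(layers, rng), desc


def _long_architecture(rng: np.random.Generator, n_in: int) -> Tuple[nn.Sequential, str]:
    layers = [
        nn.Dense(n_in, 128, rng),
        nn.BatchNorm(128),
        nn.ReLU(),
        nn.Dropout(0.2, rng),
        nn.Dense(128, 64, rng),
        nn.BatchNorm(64),
        nn.ReLU(),
        nn.Dropout(0.2, rng),
        nn.Dense(64, 32, rng),
        nn.ReLU(),
        nn.Dense(32, 1, rng),
    ]
    desc = "dense128-bn-drop0.2-dense64-bn-drop0.2-dense32-dense1"
    return nn.Sequential(layers, rng), desc


def _split_train_val(
    runner_ids: Sequence[str], rng: np.random.Generator
) -> Tuple[List[str], List[str]]:
    """Hold one training runner out for early stopping."""
    ids = sorted(set(runner_ids))
    if len(ids) < 2:
        raise ValueError("need at least two training runners")
    val = [ids[int(rng.integers(len(ids)))]]
    return [i for i in ids if i not in val], val


def train_short(
    samples: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    train_runners: Sequence[str],
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 128,
    lr: float = 1e-3,
    patience: int = 15,
) -> TrainedEstimator:
    """Fit the short-window convolutional regressor.

    ``samples`` maps runner id to (X, y) with X of shape (n, 6, 416)
    and y of shape (n, 4); only ``train_runners`` are used, with one
    runner held out for early stopping. Labels are z-standardized with
    training statistics that are frozen into the estimator.
    """
    missing = set(train_runners) - set(samples)
    if missing:
        raise ValueError(f"unknown training runners {sorted(missing)}")
    rng = np.random.default_rng(seed)
    fit_ids, val_ids = _split_train_val(train_runners, rng)
    x_tr = np.concatenate([samples[r][0] for r in fit_ids])
    y_tr = np.concatenate([samples[r][1] for r in fit_ids])
    x_va = np.concatenate([samples[r][0] for r in val_ids])
    y_va = np.concatenate([samples[r][1] for r in val_ids])

    mean, sd = y_tr.mean(axis=0), y_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    model, desc = _short_architecture(rng)
    model.fit(
        x_tr,
        (y_tr - mean) / sd,
        x_va,
        (y_va - mean) / sd,
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        patience=patience,
    )
    return TrainedEstimator(
        kind="short",
        model=model,
        architecture=desc,
        label_mean=mean,
        label_sd=sd,
        train_runners=tuple(sorted(train_runners)),
        seed=seed,
    )


def predict_short(est: TrainedEstimator, windows: np.ndarray) -> List[WindowEstimate]:
    """De-standardized per-window predictions with physiological clipping.

    Stride frequencies are clipped to (0.5, 3) Hz and duty factors to
    (0, 1); the number of clipped values is accumulated on the
    estimator. Accepts a single 6x416 window or a batch.
    """
    if est.kind != "short":
        raise ValueError("estimator is not a short-window model")
    x = np.asarray(windows, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.shape[1:] != (6, 416):
        raise ValueError(f"expected (n, 6, 416) input, got {x.shape}")
    raw = est.destandardize_labels(est.model.predict(x))
    sf = np.clip(raw[:, :2], *SF_CLIP)
    df = np.clip(raw[:, 2:], *DF_CLIP)
    est.n_clipped += int(np.sum(raw[:, :2] != sf) + np.sum(raw[:, 2:] != df))
    out = [
        WindowEstimate(
            window_start=float(i),
            window_length=SHORT_WINDOW_S,
            sf_left=float(sf[i, 0]),
            sf_right=float(sf[i, 1]),
            df_left=float(df[i, 0]),
            df_right=float(df[i, 1]),
        )
        for i in range(len(x))
    ]
    return out


def train_long(
    samples: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    train_runners: Sequence[str],
    seed: int = 0,
    epochs: int = 400,
    batch_size: int = 64,
    lr: float = 1e-3,
    patience: int = 60,
    weight_decay: float = 1e-4,
) -> TrainedEstimator:
    """Fit the long-window dense DFA-alpha regressor.

    ``samples`` maps runner id to (X, y) with X of shape (n, 6, 23) or
    (n, 138) and y of shape (n,): the reference DFA-alpha (left/right
    average) of the condition each window belongs to. Features are
    standardized with training statistics frozen into the estimator.
    """
    missing = set(train_runners) - set(samples)
    if missing:
        raise ValueError(f"unknown training runners {sorted(missing)}")
    rng = np.random.default_rng(seed)
    fit_ids, val_ids = _split_train_val(train_runners, rng)

    def _stack(ids):
        x = np.concatenate([samples[r][0].reshape(len(samples[r][0]), -1) for r in ids])
        y = np.concatenate([np.asarray(samples[r][1], dtype=float).ravel() for r in ids])
        return x, y[:, None]

    x_tr, y_tr = _stack(fit_ids)
    x_va, y_va = _stack(val_ids)
    f_mean, f_sd = x_tr.mean(axis=0), x_tr.std(axis=0)
    f_sd = np.where(f_sd > 0, f_sd, 1.0)
    mean, sd = y_tr.mean(axis=0), y_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)

    model, desc = _long_architecture(rng, x_tr.shape[1])
    model.fit(
        (x_tr - f_mean) / f_sd,
        (y_tr - mean) / sd,
        (x_va - f_mean) / f_sd,
        (y_va - mean) / sd,
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        patience=patience,
        weight_decay=weight_decay,
    )
    return TrainedEstimator(
        kind="long",
        model=model,
        architecture=desc,
        label_mean=mean,
        label_sd=sd,
        feature_mean=f_mean,
        feature_sd=f_sd,
        train_runners=tuple(sorted(train_runners)),
        seed=seed,
    )


def predict_long(est: TrainedEstimator, features) -> np.ndarray:
    """DFA-alpha predictions for a batch of 6x23 feature matrices."""
    if est.kind != "long":
        raise ValueError("estimator is not a long-window model")
    if isinstance(features, FeatureMatrix):
        features = [features]
    if isinstance(features, (list, tuple)) and isinstance(features[0], FeatureMatrix):
        x = np.vstack([f.flat() for f in features])
    else:
        x = np.asarray(features, dtype=float).reshape(len(features), -1)
    x = (x - est.feature_mean) / est.feature_sd
    return est.destandardize_labels(est.model.predict(x)).ravel()


def dfa_from_short_path(
    est: TrainedEstimator,
    thorax: IMURecording,
    analysis_seconds: Optional[float] = None,
    k_max: int = 10,
) -> VariabilityIndices:
    """Variability indices from the short model's stride-frequency path.

    Runs the short model over the condition's rolling 2-s grid, takes
    the per-second stride frequency (left/right mean) as the series,
    and applies the fractal metrics to it. This is the short-path
    strategy whose DFA-alpha the long-window model is benchmarked
    against.
    """
    starts = window_grid(thorax.duration, SHORT_WINDOW_S, SHORT_STEP_S)
    fs = thorax.sampling_rate
    n_samp = int(round(SHORT_WINDOW_S * fs))
    chans = thorax.channels().copy()
    chans[3:] /= GYRO_NORM
    xs = np.array(
        [chans[:, int(round(t * fs)) : int(round(t * fs)) + n_samp] for t in starts]
    )
    preds = predict_short(est, xs)
    sf_series = np.array([(p.sf_left + p.sf_right) / 2.0 for p in preds])
    if np.ptp(sf_series) == 0:
        from .types import DegenerateInputError

        raise DegenerateInputError("constant predicted stride-frequency sequence")
    return variability_from_stride_frequency(
        sf_series, k_max=k_max, analysis_seconds=analysis_seconds
    )


def save_estimator(est: TrainedEstimator, directory) -> None:
    """Write a model bundle (architecture, weights, statistics) as JSON text."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": est.kind,
        "architecture": est.architecture,
        "label_mean": est.label_mean.tolist(),
        "label_sd": est.label_sd.tolist(),
        "feature_mean": None if est.feature_mean is None else est.feature_mean.tolist(),
        "feature_sd": None if est.feature_sd is None else est.feature_sd.tolist(),
        "train_runners": list(est.train_runners),
        "seed": est.seed,
    }
    (d / "estimator.json").write_text(json.dumps(meta, indent=1))
    est.model.save(str(d / "weights.json"))


def load_estimator(directory) -> TrainedEstimator:
    """Reload a bundle written by :func:`save_estimator`."""
    import json
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / "estimator.json").read_text())
    rng = np.random.default_rng(meta["seed"])
    if meta["kind"] == "short":
        model, _ = _short_architecture(rng)
    else:
        model, _ = _long_architecture(rng, len(meta["feature_mean"]))
    model.load(str(d / "weights.json"))
    return TrainedEstimator(
        kind=meta["kind"],
        model=model,
        architecture=meta["architecture"],
        label_mean=np.asarray(meta["label_mean"]),
        label_sd=np.asarray(meta["label_sd"]),
        feature_mean=None if meta["feature_mean"] is None else np.asarray(meta["feature_mean"]),
        feature_sd=None if meta["feature_sd"] is None else np.asarray(meta["feature_sd"]),
        train_runners=tuple(meta["train_runners"]),
        seed=meta["seed"],
    )
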