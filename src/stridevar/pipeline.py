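"""End-to-end evaluation: synthetic cohort -> three strategies -> comparison.

Runs the full study design on a synthetic cohort: the reference
strategy (ground-truth gait events, standing in for an optoelectronic
system), the foot-IMU detection strategy, and the two thorax-IMU
machine-learning strategies (short 2-s window for SF/DF, long 120-s
window for DFA-alpha), then assembles the tidy results table consumed
by :func:`stridevar.stats.evaluate_strategies` plus headline accuracy
metrics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .estimators import (
    TrainedEstimator,
    dfa_from_short_path,
    make_short_windows,
    predict_long,
    predict_short,
    train_long,
    train_short,
)
from .events import acceleration_norm, detect_strides, temporal_variables, windowed_average
from .features import rolling_feature_windows
from .fractal import variability_from_stride_frequency
from .stats import ComparisonTable, evaluate_strategies, rmse
from .synthetic import TrialData, generate_cohort, split_by_runner
from .types import ConditionSpec

__all__ = ["run_cohort_evaluation", "EvaluationResult", "downhill_analog_conditions"]

#: scaled five-condition protocol: two downhill analogs, level, two uphill
DEFAULT_CONDITIONS = (
    ConditionSpec(speed_pct_prs=90, inclination_pct=-8),
    ConditionSpec(speed_pct_prs=90, inclination_pct=-2),
    ConditionSpec(speed_pct_prs=90, inclination_pct=0),
    ConditionSpec(speed_pct_prs=90, inclination_pct=5),
    ConditionSpec(speed_pct_prs=90, inclination_pct=8),
)


def downhill_analog_conditions(conditions: Sequence[ConditionSpec]) -> List[str]:
    """Labels of the low-Hurst (downhill) conditions in a protocol."""
    return [c.label for c in conditions if c.inclination_pct < 0]


@dataclass
class EvaluationResult:
    table: pd.DataFrame
    comparison: ComparisonTable
    metrics: Dict[str, float]
    short_model: TrainedEstimator
    long_model: TrainedEstimator
    train_runners: List[str]
    test_runners: List[str]
    conditions: List[str]


def _fractal_pair(left_sf: np.ndarray, right_sf: np.ndarray) -> Tuple[float, float]:
    """Left/right-averaged DFA-alpha and Higuchi-D of stride-frequency series."""
    vl = variability_from_stride_frequency(left_sf)
    vr = variability_from_stride_frequency(right_sf)
    return 0.5 * (vl.dfa_alpha + vr.dfa_alpha), 0.5 * (vl.higuchi_d + vr.higuchi_d)


def run_cohort_evaluation(
    seed: int = 0,
    n_runners: int = 12,
    conditions: Optional[Sequence[ConditionSpec]] = None,
    duration: float = 600.0,
    window_subsample: int = 2,
    short_epochs: int = 30,
    long_epochs: int = 400,
    noise_amplitude: float = 0.10,
    progress: bool = False,
) -> EvaluationResult:
    """Run the full three-strategy evaluation on a synthetic cohort.

    The cohort is split by runner into equal train/test halves. The
    short-window samples are taken every ``window_subsample`` seconds
    to keep one-CPU training tractable. Returns the tidy table, the
    statistical comparison, and headline metrics:

    - ``detection_sf_rel_err``: mean relative error of foot-IMU mean SF
    - ``detection_df_abs_err``: mean absolute error of foot-IMU mean DF
    - ``short_sf_rmse`` / ``short_df_rmse``: test-window RMSE of the
      short model vs reference
    - ``short_*_baseline``: same for the predict-the-training-mean model
    - ``long_dfa_rmse`` / ``long_dfa_baseline``: test RMSE of the
      long-window model's condition-level estimates (mean over the 25
      windows of a condition, matching per-condition evaluation) vs
      the reference DFA-alpha; ``long_dfa_rmse_window`` is the
      per-window variant
    - ``shortpath_dfa_rmse_downhill`` / ``long_dfa_rmse_downhill``:
      the head-to-head on the low-Hurst (downhill-analog) conditions
    """
    conditions = list(conditions) if conditions is not None else list(DEFAULT_CONDITIONS)
    cohort = generate_cohort(
        n_runners, conditions, master_seed=seed, noise_amplitude=noise_amplitude
    )
    train_ids, test_ids = split_by_runner(cohort, seed=seed + 1)

    short_samples: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    long_samples: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    rows: List[dict] = []
    trial_cache: List[dict] = []
    det_sf_errs, det_df_errs = [], []

    for k, trial in enumerate(cohort.trials):
        td: TrialData = cohort.realize(trial)
        rid, cond = trial.runner_id, trial.condition.label
        if progress:  # pragma: no cover
            print(f"[{k + 1}/{len(cohort.trials)}] {rid} {cond}")

        # --- reference strategy: exact events -> window grid + fractal
        tv_ref_l = temporal_variables(td.left_events)
        tv_ref_r = temporal_variables(td.right_events)
        ref_windows = windowed_average(tv_ref_l, tv_ref_r, duration)
        ref_alpha, ref_hgd = _fractal_pair(
            td.left_strides.stride_frequencies, td.right_strides.stride_frequencies
        )

        # --- foot-IMU strategy: detect events on the acceleration norm
        det_l = detect_strides(
            acceleration_norm(td.left_foot), cohort.sampling_rate, foot="left"
        )
        det_r = detect_strides(
            acceleration_norm(td.right_foot), cohort.sampling_rate, foot="right"
        )
        tv_det_l, tv_det_r = temporal_variables(det_l), temporal_variables(det_r)
        foot_windows = windowed_average(tv_det_l, tv_det_r, duration)
        foot_alpha, foot_hgd = _fractal_pair(
            tv_det_l["sf"].to_numpy(), tv_det_r["sf"].to_numpy()
        )
        det_sf_errs.append(
            abs(tv_det_l["sf"].mean() - td.left_strides.stride_frequencies.mean())
            / td.left_strides.stride_frequencies.mean()
        )
        det_df_errs.append(
            abs(tv_det_l["df"].mean() - td.left_strides.duty_factors.mean())
        )

        # --- short-window samples (thorax input, reference labels)
        sub = ref_windows[::window_subsample]
        x, y, valid = make_short_windows(td.thorax, sub)
        x, y = x[valid].astype(np.float32), y[valid]
        short_samples.setdefault(rid, []).append((x, y))

        # --- long-window samples (thorax features, condition-level label)
        feats = rolling_feature_windows(td.thorax)
        fx = np.vstack([f.flat() for f in feats]).astype(np.float32)
        fy = np.full(len(feats), ref_alpha)
        long_samples.setdefault(rid, []).append((fx, fy))

        for w_ref, w_foot in zip(ref_windows, foot_windows):
            if not (w_ref.valid and w_foot.valid):
                continue
            u = int(w_ref.window_start)
            for var, rv, fv in (
                ("SF", 0.5 * (w_ref.sf_left + w_ref.sf_right), 0.5 * (w_foot.sf_left + w_foot.sf_right)),
                ("DF", 0.5 * (w_ref.df_left + w_ref.df_right), 0.5 * (w_foot.df_left + w_foot.df_right)),
            ):
                rows.append(dict(runner=rid, condition=cond, variable=var,
                                 strategy="reference", unit=u, value=rv))
                rows.append(dict(runner=rid, condition=cond, variable=var,
                                 strategy="foot_imu", unit=u, value=fv))
        rows.append(dict(runner=rid, condition=cond, variable="DFA", strategy="reference",
                         unit=-1, value=ref_alpha))
        rows.append(dict(runner=rid, condition=cond, variable="DFA", strategy="foot_imu",
                         unit=-1, value=foot_alpha))
        rows.append(dict(runner=rid, condition=cond, variable="HGD", strategy="reference",
                         unit=-1, value=ref_hgd))
        rows.append(dict(runner=rid, condition=cond, variable="HGD", strategy="foot_imu",
                         unit=-1, value=foot_hgd))
        trial_cache.append(
            dict(trial=trial, ref_alpha=ref_alpha, x=x, y=y,
                 window_starts=[w.window_start for w, v in zip(sub, valid) if v],
                 fx=fx)
        )
        del td

    # ------------------------------------------------------------------
    # train the two thorax models on the training half
    merged_short = {
        r: (np.concatenate([x for x, _ in lst]), np.concatenate([y for _, y in lst]))
        for r, lst in short_samples.items()
    }
    merged_long = {
        r: (np.concatenate([x for x, _ in lst]), np.concatenate([y for _, y in lst]))
        for r, lst in long_samples.items()
    }
    short_model = train_short(merged_short, train_ids, seed=seed, epochs=short_epochs)
    long_model = train_long(merged_long, train_ids, seed=seed, epochs=long_epochs)

    # predict-the-training-mean baselines
    y_train = np.concatenate([merged_short[r][1] for r in train_ids])
    base_short = y_train.mean(axis=0)
    alpha_train_mean = float(
        np.concatenate([merged_long[r][1] for r in train_ids]).mean()
    )

    # ------------------------------------------------------------------
    # evaluate on the test half
    sf_pred, sf_ref, df_pred, df_ref = [], [], [], []
    long_pred_all, long_ref_all = [], []
    long_window_sq: List[float] = []
    long_sq_by_cond: Dict[str, List[float]] = {}
    shortpath_sq_by_cond: Dict[str, List[float]] = {}

    for entry in trial_cache:
        trial = entry["trial"]
        rid, cond = trial.runner_id, trial.condition.label
        if rid not in test_ids:
            continue
        preds = predict_short(short_model, entry["x"].astype(np.float64))
        for p, yv, u in zip(preds, entry["y"], entry["window_starts"]):
            sf_p = 0.5 * (p.sf_left + p.sf_right)
            df_p = 0.5 * (p.df_left + p.df_right)
            sf_pred.append(sf_p)
            sf_ref.append(0.5 * (yv[0] + yv[1]))
            df_pred.append(df_p)
            df_ref.append(0.5 * (yv[2] + yv[3]))
            for var, val in (("SF", sf_p), ("DF", df_p)):
                rows.append(dict(runner=rid, condition=cond, variable=var,
                                 strategy="nn_short", unit=int(u), value=val))
        a_pred = predict_long(long_model, entry["fx"].astype(np.float64))
        # one estimate per condition: mean of the 25 window predictions
        a_trial = float(np.mean(a_pred))
        long_pred_all.append(a_trial)
        long_ref_all.append(entry["ref_alpha"])
        long_window_sq.extend((np.asarray(a_pred) - entry["ref_alpha"]) ** 2)
        long_sq_by_cond.setdefault(cond, []).append((a_trial - entry["ref_alpha"]) ** 2)
        rows.append(dict(runner=rid, condition=cond, variable="DFA", strategy="nn_long",
                         unit=-1, value=a_trial))

        # short-path DFA: fractal metrics on the predicted SF sequence
        td = cohort.realize(trial)
        sp = dfa_from_short_path(short_model, td.thorax)
        shortpath_sq_by_cond.setdefault(cond, []).append(
            (sp.dfa_alpha - entry["ref_alpha"]) ** 2
        )
        rows.append(dict(runner=rid, condition=cond, variable="DFA", strategy="nn_short_path",
                         unit=-1, value=float(sp.dfa_alpha)))
        rows.append(dict(runner=rid, condition=cond, variable="HGD", strategy="nn_short_path",
                         unit=-1, value=float(sp.higuchi_d)))
        del td

    downhill = downhill_analog_conditions(conditions)
    metrics = {
        "detection_sf_rel_err": float(np.mean(det_sf_errs)),
        "detection_df_abs_err": float(np.mean(det_df_errs)),
        "short_sf_rmse": rmse(sf_pred, sf_ref),
        "short_df_rmse": rmse(df_pred, df_ref),
        "short_sf_baseline": rmse(np.full(len(sf_ref), 0.5 * (base_short[0] + base_short[1])), sf_ref),
        "short_df_baseline": rmse(np.full(len(df_ref), 0.5 * (base_short[2] + base_short[3])), df_ref),
        "long_dfa_rmse": rmse(long_pred_all, long_ref_all),
        "long_dfa_rmse_window": float(np.sqrt(np.mean(long_window_sq))),
        "long_dfa_baseline": rmse(np.full(len(long_ref_all), alpha_train_mean), long_ref_all),
        "long_dfa_rmse_downhill": float(
            np.sqrt(np.mean(np.concatenate([long_sq_by_cond[c] for c in downhill])))
        )
        if downhill
        else np.nan,
        "shortpath_dfa_rmse_downhill": float(
            np.sqrt(np.mean(np.concatenate([
                np.atleast_1d(shortpath_sq_by_cond[c]) for c in downhill
            ])))
        )
        if downhill
        else np.nan,
    }

    table = pd.DataFrame(rows)
    comparison = evaluate_strategies(table, reference="reference", test_runners=test_ids)
    return EvaluationResult(
        table=table,
        comparison=comparison,
        metrics=metrics,
        short_model=short_model,
        long_model=long_model,
        train_runners=train_ids,
        test_runners=test_ids,
        conditions=[c.label for c in conditions],
    )
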