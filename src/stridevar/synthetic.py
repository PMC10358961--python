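"""Synthetic runner cohorts: stride series and IMU signal synthesis.

The generator produces, for each runner x condition, a pair of
per-foot stride-interval series with prescribed mean, coefficient of
variation and long-range correlation (Hurst exponent), and thorax +
foot inertial recordings consistent with those strides. Waveforms are
analytic raised-cosine impacts, not a biomechanical model: only the
event geometry the downstream detectors rely on is contractual.

Condition-level means for stride frequency and duty factor follow the
ranges reported for treadmill running at 80-120 % of preferred running
speed and slopes up to +-8 % (SF ~ 1.35-1.45 Hz, DF ~ 0.36-0.45);
inclination perturbs the generating Hurst exponent (downhill lower,
uphill higher) as a simulator convention echoing the direction of the
uphill/downhill variability contrast, not a physiological claim.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .noise import fractional_gaussian_noise, pink_noise
from .types import (
    ConditionSpec,
    GaitEventSeries,
    IMURecording,
    RunnerSpec,
    StrideSeries,
)

__all__ = [
    "generate_stride_series",
    "generate_stride_pair",
    "synthesize_foot_imu",
    "synthesize_thorax_imu",
    "generate_cohort",
    "CohortDataset",
    "TrialSpec",
    "TrialData",
    "default_conditions",
    "split_by_runner",
]

# impact-waveform constants (g unless noted); amplitudes well above the
# default sensor noise so the peak structure survives at realistic SNR
FOOTSTRIKE_AMP = 8.0
FOOTSTRIKE_WIDTH = 0.035  # half-width, s
TOEOFF_AMP = 3.5
TOEOFF_WIDTH = 0.030
SWING_AMP = 0.35
THORAX_ML_AMP = 0.30
THORAX_AP_AMP = 0.25  # braking/propulsion couple, g
THORAX_DF_GAIN = 0.40  # vertical step amplitude = gain / duty factor
GYRO_SCALE = 30.0  # native sensor units
GYRO_ROLL_AMP = 25.0  # trunk roll rate, sensor units
GYRO_PITCH_AMP = 20.0
GYRO_YAW_AMP = 12.0

# fraction of non-positive intervals above which the parameters are rejected
MAX_NONPOS_FRACTION = 0.01
REDRAW_ATTEMPTS = 10


def _rng(spec: RunnerSpec, stream: str) -> np.random.Generator:
    key = [spec.seed] + [ord(c) for c in stream]
    return np.random.default_rng(np.random.SeedSequence(key))


def _correlated_unit_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with DFA exponent ~ hurst; H=1 means 1/f noise."""
    if hurst >= 1.0:
        return pink_noise(n, rng)
    return fractional_gaussian_noise(n, hurst, rng)


def generate_stride_series(
    n_strides: int,
    spec: RunnerSpec,
    foot: str = "left",
    start_time: float = 0.35,
) -> StrideSeries:
    """Stride-interval series with prescribed mean, CV and Hurst exponent.

    Intervals are mean_interval * (1 + cv * z) with z unit-variance
    fractional Gaussian noise (exact circulant-embedding synthesis) of
    Hurst ``spec.hurst``; contact times are per-stride duty-factor
    draws times the interval. The right foot uses an independent
    sub-stream of the runner seed and starts half a stride later.
    """
    if n_strides < 64:
        raise ValueError("need at least 64 strides for a usable series")
    # under a Gaussian model the non-positive fraction is Phi(-1/cv)
    from scipy.stats import norm

    if spec.stride_cv > 0 and norm.cdf(-1.0 / spec.stride_cv) > MAX_NONPOS_FRACTION:
        raise ValueError(
            f"stride_cv={spec.stride_cv} would make >1% of intervals non-positive"
        )

    rng = _rng(spec, f"strides-{foot}")
    mean_interval = 1.0 / spec.mean_stride_frequency
    if spec.stride_cv == 0:
        intervals = np.full(n_strides, mean_interval)
    else:
        for _ in range(REDRAW_ATTEMPTS):
            z = _correlated_unit_noise(n_strides, spec.hurst, rng)
            intervals = mean_interval * (1.0 + spec.stride_cv * z)
            if np.all(intervals > 0):
                break
        else:
            raise ValueError("could not draw an all-positive interval series")

    duty = rng.normal(spec.mean_duty_factor, spec.duty_sd, n_strides)
    duty = np.clip(duty, 0.05, 0.95)
    offset = 0.5 * mean_interval if foot == "right" else 0.0
    starts = start_time + offset + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    return StrideSeries(
        foot=foot,
        start_times=starts,
        intervals=intervals,
        contact_times=duty * intervals,
    )


def generate_stride_pair(
    n_strides: int, spec: RunnerSpec, start_time: float = 0.35
) -> Tuple[StrideSeries, StrideSeries]:
    """Phase-locked left/right stride series for one runner.

    A runner's feet alternate: the right strike falls near the middle
    of the left stride. The right series therefore shares the left
    series' interval structure (so both feet carry the same long-range
    correlation) with a small independent phase jitter and independent
    duty-factor draws, rather than being an independent draw that would
    drift out of phase over a long trial.
    """
    left = generate_stride_series(n_strides, spec, foot="left", start_time=start_time)
    rng = _rng(spec, "right-phase")
    jitter = rng.normal(0.0, 0.02, n_strides)
    phase = 0.5 * left.intervals * (1.0 + jitter)
    phase = np.clip(phase, 0.15 * left.intervals, 0.85 * left.intervals)
    r_starts = left.start_times + phase
    r_intervals = np.append(np.diff(r_starts), left.intervals[-1])
    duty = np.clip(
        rng.normal(spec.mean_duty_factor, spec.duty_sd, n_strides), 0.05, 0.95
    )
    right = StrideSeries(
        foot="right",
        start_times=r_starts,
        intervals=r_intervals,
        contact_times=duty * r_intervals,
    )
    return left, right


def _raised_cosines(
    t: np.ndarray, centers: np.ndarray, amps: np.ndarray | float, half_width: float
) -> np.ndarray:
    """Sum of raised-cosine bumps, each peaking exactly at its center."""
    out = np.zeros_like(t)
    amps = np.broadcast_to(np.asarray(amps, dtype=float), centers.shape)
    dt = t[1] - t[0]
    w = int(math.ceil(half_width / dt))
    for c, a in zip(centers, amps):
        i0 = max(int((c - half_width - t[0]) / dt) - 1, 0)
        i1 = min(i0 + 2 * w + 3, len(t))
        seg = t[i0:i1]
        mask = np.abs(seg - c) < half_width
        out[i0:i1][mask] += 0.5 * a * (1.0 + np.cos(np.pi * (seg[mask] - c) / half_width))
    return out


def _bandlimited_noise(n: int, fs: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """White noise smoothed to ~20 Hz bandwidth, scaled to sd ``amp``."""
    from scipy.ndimage import uniform_filter1d

    x = rng.standard_normal(n)
    x = uniform_filter1d(x, max(int(fs / 20), 1))
    sd = x.std()
    return amp * x / sd if sd > 0 else x * 0.0


def synthesize_foot_imu(
    strides: StrideSeries,
    spec: RunnerSpec,
    fs: float = 208.0,
    duration: Optional[float] = None,
) -> Tuple[IMURecording, GaitEventSeries]:
    """Foot recording whose acceleration norm encodes the gait events.

    Per stride, the norm carries a dominant impact peak at the foot
    strike and a smaller, clearly separated peak at the toe off (the
    two largest local maxima of the cycle, in that order), low
    swing-phase oscillation elsewhere, plus additive sensor noise of
    amplitude ``spec.noise_amplitude``. Ground-truth events are
    returned alongside.
    """
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    events = strides.to_events()
    if duration is None:
        duration = float(events.foot_strikes[-1] + 0.5)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    a_z = np.ones(n)  # gravity baseline, g
    a_z += _raised_cosines(t, events.foot_strikes, FOOTSTRIKE_AMP, FOOTSTRIKE_WIDTH)
    a_z += _raised_cosines(t, events.toe_offs, TOEOFF_AMP, TOEOFF_WIDTH)
    a_z += SWING_AMP * np.sin(2.0 * np.pi * spec.mean_stride_frequency * t)
    a_x = 0.15 * np.sin(2.0 * np.pi * spec.mean_stride_frequency * t + 0.7)
    a_y = 0.12 * np.cos(2.0 * np.pi * spec.mean_stride_frequency * t + 1.9)

    rng = _rng(spec, f"foot-imu-{strides.foot}")
    acc = np.vstack([a_x, a_y, a_z])
    if spec.noise_amplitude > 0:
        acc = acc + rng.normal(0.0, spec.noise_amplitude, acc.shape)
    gyro = np.vstack(
        [
            _bandlimited_noise(n, fs, GYRO_SCALE, rng)
            + 20.0 * np.sin(2.0 * np.pi * spec.mean_stride_frequency * t + ph)
            for ph in (0.0, 1.1, 2.3)
        ]
    )
    rec = IMURecording(
        placement=f"{strides.foot}_foot", sampling_rate=fs, acc=acc, gyro=gyro
    )
    return rec, events


def synthesize_thorax_imu(
    left: StrideSeries,
    right: StrideSeries,
    spec: RunnerSpec,
    fs: float = 208.0,
    duration: Optional[float] = None,
) -> IMURecording:
    """Thorax recording driven by the interleaved left/right steps.

    The vertical channel oscillates at step frequency (twice the stride
    frequency): each step contributes a raised-cosine burst spanning
    that stride's contact time with peak amplitude inversely
    proportional to its duty factor (shorter contact, sharper impact).
    The mediolateral channel alternates sign with the stance foot; the
    anteroposterior channel carries the step-locked braking/propulsion
    couple. The angular-velocity channels carry step-locked trunk
    roll/pitch/yaw oscillation (roll and yaw alternate with the stance
    foot, pitch repeats every step) on top of band-limited noise, as
    real trunk kinematics do.
    """
    steps: List[Tuple[float, float, float, int]] = []  # (strike, contact, df, side)
    for series, side in ((left, +1), (right, -1)):
        for s, c, d in zip(series.start_times, series.contact_times, series.duty_factors):
            steps.append((float(s), float(c), float(d), side))
    steps.sort(key=lambda x: x[0])
    sides = [s[3] for s in steps]
    if any(a == b for a, b in zip(sides, sides[1:])):
        raise ValueError("left and right foot strikes must interleave")

    if duration is None:
        duration = float(
            max(left.start_times[-1] + left.intervals[-1], right.start_times[-1] + right.intervals[-1])
            + 0.5
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    a_z = np.ones(n)
    a_x = np.zeros(n)
    a_y = np.zeros(n)
    roll = np.zeros(n)  # w_x: alternates with stance foot, stride-periodic
    pitch = np.zeros(n)  # w_y: repeats every step
    yaw = np.zeros(n)  # w_z: small, alternates with foot
    dt = 1.0 / fs
    for strike, contact, df, side in steps:
        half = contact / 2.0
        center = strike + half
        amp = THORAX_DF_GAIN / df
        i0 = max(int((center - half) / dt) - 1, 0)
        i1 = min(int((center + half) / dt) + 2, n)
        seg = t[i0:i1]
        mask = np.abs(seg - center) < half
        phase = np.pi * (seg[mask] - center) / half  # -pi..pi over the contact
        bump = 0.5 * (1.0 + np.cos(phase))
        a_z[i0:i1][mask] += amp * bump
        a_x[i0:i1][mask] += side * THORAX_ML_AMP * bump
        # braking then propulsion: odd-symmetric within the contact
        a_y[i0:i1][mask] += -THORAX_AP_AMP * np.sin(phase)
        roll[i0:i1][mask] += side * GYRO_ROLL_AMP * bump
        pitch[i0:i1][mask] += GYRO_PITCH_AMP * np.sin(phase)
        yaw[i0:i1][mask] += side * GYRO_YAW_AMP * np.sin(phase)

    rng = _rng(spec, "thorax-imu")
    acc = np.vstack([a_x, a_y, a_z])
    if spec.noise_amplitude > 0:
        acc = acc + rng.normal(0.0, spec.noise_amplitude, acc.shape)
    gyro_noise_sd = spec.noise_amplitude * GYRO_SCALE
    gyro = np.vstack(
        [
            osc + _bandlimited_noise(n, fs, gyro_noise_sd, rng)
            for osc in (roll, pitch, yaw)
        ]
    )
    return IMURecording(placement="thorax", sampling_rate=fs, acc=acc, gyro=gyro)


# ---------------------------------------------------------------------------
# cohort generation


#: condition-level generating means: label -> (SF Hz, DF fraction, Hurst).
#: SF/DF echo reference values reported for treadmill cohorts (DF falls
#: from ~0.45 at 80 %PRS to ~0.37 at 120 %PRS; SF rises 1.36->1.44 Hz);
#: the inclination->Hurst map (downhill 0.55 ... uphill 0.75) is the
#: simulator's convention for the uphill/downhill variability contrast.
CONDITION_MEANS: Dict[str, Tuple[float, float, float]] = {
    "80%PRS": (1.359, 0.448, 0.69),
    "90%PRS": (1.369, 0.417, 0.70),
    "100%PRS": (1.386, 0.401, 0.73),
    "110%PRS": (1.405, 0.381, 0.75),
    "120%PRS": (1.435, 0.366, 0.77),
    "-8%": (1.355, 0.412, 0.55),
    "-5%": (1.368, 0.414, 0.60),
    "-2%": (1.386, 0.423, 0.65),
    "+2%": (1.384, 0.426, 0.72),
    "+5%": (1.393, 0.428, 0.74),
    "+8%": (1.405, 0.423, 0.75),
}

#: between-runner variability of the condition means
RUNNER_SF_REL_SD = 0.04
RUNNER_DF_SD = 0.02
RUNNER_HURST_SD = 0.02


def default_conditions(duration: float = 600.0) -> List[ConditionSpec]:
    """The full 11-condition protocol: 5 speeds plus 6 slopes at 90 %PRS."""
    speeds = [ConditionSpec(speed_pct_prs=s, duration=duration) for s in (80, 90, 100, 110, 120)]
    slopes = [
        ConditionSpec(speed_pct_prs=90, inclination_pct=i, duration=duration)
        for i in (-8, -5, -2, 2, 5, 8)
    ]
    return speeds + slopes


@dataclass(frozen=True)
class TrialSpec:
    """One runner x condition cell: everything needed to realize signals."""

    runner_id: str
    condition: ConditionSpec
    spec: RunnerSpec


@dataclass
class TrialData:
    """Materialized signals and ground truth for one trial."""

    trial: TrialSpec
    thorax: IMURecording
    left_foot: IMURecording
    right_foot: IMURecording
    left_strides: StrideSeries
    right_strides: StrideSeries
    left_events: GaitEventSeries
    right_events: GaitEventSeries


@dataclass
class CohortDataset:
    """Lazy synthetic cohort: trial specs plus on-demand signal synthesis.

    Recordings for a full cohort are large, so they are synthesized per
    trial via :meth:`realize` rather than held in memory.
    """

    trials: List[TrialSpec]
    sampling_rate: float = 208.0

    @property
    def runner_ids(self) -> List[str]:
        seen: List[str] = []
        for tr in self.trials:
            if tr.runner_id not in seen:
                seen.append(tr.runner_id)
        return seen

    def realize(self, trial: TrialSpec) -> TrialData:
        cond = trial.condition
        spec = trial.spec
        # enough strides to cover the condition duration with margin
        n_strides = int(cond.duration * spec.mean_stride_frequency * 1.05) + 8
        left, right = generate_stride_pair(n_strides, spec)
        left = _truncate(left, cond.duration)
        right = _truncate(right, cond.duration)
        fs = self.sampling_rate
        left_rec, left_ev = synthesize_foot_imu(left, spec, fs, duration=cond.duration)
        right_rec, right_ev = synthesize_foot_imu(right, spec, fs, duration=cond.duration)
        thorax = synthesize_thorax_imu(left, right, spec, fs, duration=cond.duration)
        return TrialData(
            trial=trial,
            thorax=thorax,
            left_foot=left_rec,
            right_foot=right_rec,
            left_strides=left,
            right_strides=right,
            left_events=left_ev,
            right_events=right_ev,
        )

    def __iter__(self):
        return (self.realize(tr) for tr in self.trials)


def _truncate(series: StrideSeries, duration: float) -> StrideSeries:
    keep = series.start_times + series.intervals <= duration
    if not np.any(keep):
        raise ValueError("duration too short for a single stride")
    return StrideSeries(
        foot=series.foot,
        start_times=series.start_times[keep],
        intervals=series.intervals[keep],
        contact_times=series.contact_times[keep],
    )


def generate_cohort(
    n_runners: int,
    conditions: Optional[Sequence[ConditionSpec]] = None,
    master_seed: int = 0,
    noise_amplitude: float = 0.10,
) -> CohortDataset:
    """A cohort of runners across conditions, deterministic in the seed.

    Per runner, condition-level SF/DF/Hurst means are perturbed by
    runner-specific offsets; the stride-interval CV is drawn uniformly
    in 1-2 %, typical of steady treadmill running.
    """
    if n_runners < 2:
        raise ValueError("need at least two runners")
    if conditions is None:
        conditions = default_conditions()
    ss = np.random.SeedSequence(master_seed)
    trials: List[TrialSpec] = []
    for r, child in enumerate(ss.spawn(n_runners)):
        rng = np.random.default_rng(child)
        runner_id = f"R{r:02d}"
        sf_off = rng.normal(0.0, RUNNER_SF_REL_SD)
        df_off = rng.normal(0.0, RUNNER_DF_SD)
        h_off = rng.normal(0.0, RUNNER_HURST_SD)
        cv = rng.uniform(0.010, 0.020)
        for c, cond in enumerate(conditions):
            sf_mean, df_mean, hurst = CONDITION_MEANS[cond.label]
            spec = RunnerSpec(
                runner_id=runner_id,
                mean_stride_frequency=sf_mean * (1.0 + sf_off),
                stride_cv=cv,
                hurst=float(np.clip(hurst + h_off, 0.05, 0.98)),
                mean_duty_factor=float(np.clip(df_mean + df_off, 0.10, 0.90)),
                duty_sd=0.010,
                noise_amplitude=noise_amplitude,
                seed=int(child.generate_state(1)[0] % (2**31) + 1000 * c),
            )
            trials.append(TrialSpec(runner_id=runner_id, condition=cond, spec=spec))
    return CohortDataset(trials=trials)


def split_by_runner(
    dataset: CohortDataset, n_train: Optional[int] = None, seed: int = 0
) -> Tuple[List[str], List[str]]:
    """Random split of runner ids into disjoint train/test halves."""
    ids = dataset.runner_ids
    if n_train is None:
        n_train = len(ids) // 2
    if not (0 < n_train < len(ids)):
        raise ValueError("n_train must leave runners in both splits")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(ids))
    return sorted(perm[:n_train]), sorted(perm[n_train:])
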