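"""Core containers shared across the pipeline.

The pipeline moves data through a small set of shapes: raw six-channel
inertial recordings, per-foot gait-event series, per-foot stride series,
windowed estimates on a rolling grid, and scalar variability indices.
All containers are plain dataclasses over numpy arrays.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

PLACEMENTS = ("thorax", "left_foot", "right_foot")


class DegenerateInputError(ValueError):
    """Raised when a series is constant or otherwise uninformative."""


class DetectionError(RuntimeError):
    """Raised when gait-event detection cannot find a plausible stride pattern."""


@dataclass(frozen=True)
class RunnerSpec:
    """Generating parameters for one synthetic runner in one condition.

    mean_stride_frequency is in Hz, mean_duty_factor and duty_sd are
    fractions of the stride cycle, stride_cv is the coefficient of
    variation of stride intervals, hurst controls the long-range
    correlation of the stride-interval series (H=1 requests 1/f noise),
    noise_amplitude is the additive sensor noise in g (accelerations)
    and in native sensor units (angular velocities).
    """

    runner_id: str
    mean_stride_frequency: float = 1.40
    stride_cv: float = 0.015
    hurst: float = 0.70
    mean_duty_factor: float = 0.40
    duty_sd: float = 0.01
    noise_amplitude: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_stride_frequency <= 0:
            raise ValueError("mean_stride_frequency must be positive")
        if not (0.0 < self.mean_duty_factor < 1.0):
            raise ValueError("mean_duty_factor must lie in (0, 1)")
        if self.stride_cv < 0:
            raise ValueError("stride_cv must be non-negative")
        if not (0.0 < self.hurst <= 1.0):
            raise ValueError("hurst must lie in (0, 1]")


@dataclass(frozen=True)
class ConditionSpec:
    """One treadmill condition: a speed level (%PRS) at a treadmill slope.

    Speed conditions run at 0 % inclination; inclination conditions run
    at 90 %PRS, mirroring a crossed speed/slope treadmill protocol.
    """

    speed_pct_prs: int = 90
    inclination_pct: int = 0
    duration: float = 600.0

    def __post_init__(self) -> None:
        if self.inclination_pct != 0 and self.speed_pct_prs != 90:
            raise ValueError("non-level conditions must be run at 90 %PRS")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def label(self) -> str:
        if self.inclination_pct != 0:
            return f"{self.inclination_pct:+d}%"
        return f"{self.speed_pct_prs}%PRS"


@dataclass
class IMURecording:
    """Six-channel inertial recording at a fixed sampling rate.

    ``acc`` holds (a_x, a_y, a_z) in g; ``gyro`` holds (w_x, w_y, w_z)
    in native sensor units. Both are arrays of shape (3, n_samples).
    """

    placement: str
    sampling_rate: float
    acc: np.ndarray
    gyro: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"placement must be one of {PLACEMENTS}")
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.shape != self.gyro.shape or self.acc.ndim != 2 or self.acc.shape[0] != 3:
            raise ValueError("acc and gyro must both have shape (3, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def channels(self) -> np.ndarray:
        """All six channels stacked (a_x, a_y, a_z, w_x, w_y, w_z) x n."""
        return np.vstack([self.acc, self.gyro])


@dataclass
class GaitEventSeries:
    """Per-foot foot-strike and toe-off instants, in seconds.

    Events must alternate: strike_i < toeoff_i < strike_{i+1}.
    ``toe_offs`` has one element fewer than or equal to ``foot_strikes``;
    only toe-offs bracketed by two strikes define complete strides.
    """

    foot: str
    foot_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ValueError("foot must be 'left' or 'right'")
        self.foot_strikes = np.asarray(self.foot_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        self.validate()

    def validate(self) -> None:
        fs, to = self.foot_strikes, self.toe_offs
        if np.any(np.diff(fs) <= 0) or np.any(np.diff(to) <= 0):
            raise ValueError("event times must be strictly increasing")
        n = min(len(fs) - 1, len(to))
        if n > 0:
            if np.any(to[:n] <= fs[:n]) or np.any(to[:n] >= fs[1 : n + 1]):
                raise ValueError("events must alternate strike < toe-off < next strike")

    @property
    def n_strides(self) -> int:
        return max(len(self.foot_strikes) - 1, 0)


@dataclass
class StrideSeries:
    """Ordered per-foot stride intervals and contact times.

    ``start_times`` are foot-strike instants; interval_i spans
    start_times[i] .. start_times[i] + intervals[i]. Contact times are
    the in-stride ground-contact durations, so duty factor is
    contact_times / intervals.
    """

    foot: str
    start_times: np.ndarray
    intervals: np.ndarray
    contact_times: np.ndarray

    def __post_init__(self) -> None:
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.contact_times = np.asarray(self.contact_times, dtype=float)
        if not (len(self.start_times) == len(self.intervals) == len(self.contact_times)):
            raise ValueError("start_times, intervals and contact_times must align")
        if np.any(self.intervals <= 0):
            raise ValueError("stride intervals must be positive")
        if np.any(self.contact_times <= 0) or np.any(self.contact_times >= self.intervals):
            raise ValueError("contact times must lie strictly inside the stride interval")

    @property
    def n_strides(self) -> int:
        return len(self.intervals)

    @property
    def stride_frequencies(self) -> np.ndarray:
        return 1.0 / self.intervals

    @property
    def duty_factors(self) -> np.ndarray:
        return self.contact_times / self.intervals

    def to_events(self) -> GaitEventSeries:
        """Exact per-foot event series implied by the strides."""
        strikes = np.append(self.start_times, self.start_times[-1] + self.intervals[-1])
        toe_offs = self.start_times + self.contact_times
        return GaitEventSeries(foot=self.foot, foot_strikes=strikes, toe_offs=toe_offs)

    @classmethod
    def from_events(cls, events: GaitEventSeries) -> "StrideSeries":
        """Per-stride intervals/contacts from an alternating event series."""
        fs, to = events.foot_strikes, events.toe_offs
        if len(fs) < 2:
            raise ValueError("need at least two foot strikes")
        n = min(len(fs) - 1, len(to))
        return cls(
            foot=events.foot,
            start_times=fs[:n],
            intervals=np.diff(fs)[:n],
            contact_times=to[:n] - fs[:n],
        )


@dataclass
class WindowEstimate:
    """Per-foot stride frequency and duty factor over one analysis window."""

    window_start: float
    window_length: float
    sf_left: float
    sf_right: float
    df_left: float
    df_right: float

    @property
    def valid(self) -> bool:
        return bool(
            np.all(np.isfinite([self.sf_left, self.sf_right, self.df_left, self.df_right]))
        )

    def as_vector(self) -> np.ndarray:
        """The 4-vector (sf_left, sf_right, df_left, df_right)."""
        return np.array([self.sf_left, self.sf_right, self.df_left, self.df_right])


@dataclass
class VariabilityIndices:
    """DFA scaling exponent and Higuchi fractal dimension with settings."""

    dfa_alpha: float = np.nan
    higuchi_d: float = np.nan
    n_points: int = 0
    dfa_scales: Optional[np.ndarray] = None
    k_max: Optional[int] = None
    fit_r2: float = np.nan
    analysis_seconds: Optional[float] = None
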