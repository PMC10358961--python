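"""Gait-event detection and temporal variables from foot-worn IMUs.

Foot strikes are the dominant peaks of the acceleration norm; toe offs
are the largest secondary norm peak inside each stride (the
norm-of-accelerations variant of instep-IMU event detection, which is
more reliable than the vertical-acceleration-peak alternative, kept
here behind a flag for comparison). From the alternating event series,
per-stride stride frequency and duty factor follow by arithmetic; a
rolling window grid (2 s stepped by 1 s by default) averages them into
the estimates used as reference labels and for paired comparison.
"""
from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .types import DetectionError, GaitEventSeries, IMURecording, WindowEstimate

__all__ = [
    "acceleration_norm",
    "detect_strides",
    "temporal_variables",
    "windowed_average",
    "window_grid",
]

#: minimum peak separation as a fraction of the stride interval
MIN_SEPARATION_FRACTION = 0.6
#: prominence threshold in median-absolute-deviations above the median
PROMINENCE_MADS = 3.0
#: plausible stride-frequency band for the spectral bootstrap, Hz
SF_BAND = (0.5, 3.0)
#: fraction of the stride interval excluded around strikes when
#: searching for the toe-off peak
TOEOFF_SEARCH = (0.15, 0.80)
#: maximum stride-interval coefficient of variation accepted as running
MAX_INTERVAL_CV = 0.30
#: minimum impact/toe-off median peak-height ratio for a running trace
MIN_HEIGHT_RATIO = 1.5


def acceleration_norm(rec: IMURecording) -> np.ndarray:
    """Per-sample Euclidean norm of the three acceleration channels."""
    return np.sqrt(np.sum(rec.acc**2, axis=0))


def detect_strides(
    norm: np.ndarray,
    fs: float,
    expected_sf: Optional[float] = None,
    foot: str = "left",
) -> GaitEventSeries:
    """Foot strikes and toe offs from an acceleration-norm trace.

    Strikes are norm peaks passing a scale-free prominence threshold
    (3 median-absolute-deviations above the median) with minimum
    separation 0.6 x the stride interval; the toe off of each stride is
    the largest norm maximum in the interior of the stride. Implausible
    outputs (too few strikes, erratic intervals) raise DetectionError
    rather than returning a silently wrong series.
    """
    norm = np.asarray(norm, dtype=float)
    if len(norm) < 5 * fs:
        raise DetectionError("need at least 5 s of signal")
    med = np.median(norm)
    mad = np.median(np.abs(norm - med))
    height = med + PROMINENCE_MADS * max(mad, 1e-12)
    # coarse pass: impact and toe-off peaks together; their heights must
    # separate into two classes for the trace to look like running
    coarse, props = find_peaks(
        norm, height=height, distance=max(int(fs / (2 * SF_BAND[1])), 1)
    )
    if len(coarse) < 5:
        raise DetectionError("too few peaks to bootstrap a stride period")
    h = props["peak_heights"]
    theta = 0.5 * (np.percentile(h, 90) + np.percentile(h, 10))
    tall, short = h[h >= theta], h[h < theta]
    if len(tall) < 5 or len(short) == 0 or np.median(tall) < MIN_HEIGHT_RATIO * np.median(short):
        raise DetectionError("no impact/toe-off peak-height separation: not a running trace")
    if expected_sf:
        period = 1.0 / expected_sf
    else:
        period = float(np.median(np.diff(coarse[h >= theta]))) / fs
        if not (1.0 / SF_BAND[1] <= period <= 1.0 / SF_BAND[0]):
            raise DetectionError(f"bootstrapped stride period {period:.2f}s implausible")
    distance = max(int(MIN_SEPARATION_FRACTION * period * fs), 1)
    peaks, _ = find_peaks(norm, height=height, distance=distance)
    # strikes half-buried at the signal edges are not trustworthy
    margin = 0.5 * period * fs
    peaks = peaks[(peaks >= margin) & (peaks <= len(norm) - margin)]
    if len(peaks) < 5:
        raise DetectionError(f"only {len(peaks)} candidate strikes found")

    strikes = peaks / fs
    intervals = np.diff(strikes)
    cv = intervals.std() / intervals.mean()
    if cv > MAX_INTERVAL_CV:
        raise DetectionError(
            f"stride intervals too erratic (cv={cv:.2f}) to be running"
        )

    toe_offs: List[float] = []
    kept: List[int] = []
    for i in range(len(peaks) - 1):
        lo = peaks[i] + int(TOEOFF_SEARCH[0] * (peaks[i + 1] - peaks[i]))
        hi = peaks[i] + int(TOEOFF_SEARCH[1] * (peaks[i + 1] - peaks[i]))
        if hi <= lo + 1:
            continue
        seg = norm[lo:hi]
        toe_offs.append((lo + int(np.argmax(seg))) / fs)
        kept.append(i)
    if len(kept) < 2:
        raise DetectionError("could not locate toe-offs")
    if kept != list(range(kept[0], kept[-1] + 1)):
        raise DetectionError("toe-off search failed inside the stride sequence")
    # keep only strikes whose stride has a located toe-off, plus the closing one
    last = kept[-1] + 1
    strikes = strikes[kept[0] : last + 1]
    return GaitEventSeries(foot=foot, foot_strikes=strikes, toe_offs=np.array(toe_offs))


def detect_strides_vertical(
    rec: IMURecording, fs: Optional[float] = None, expected_sf: Optional[float] = None
) -> GaitEventSeries:
    """Vertical-acceleration-peak variant of the detector (comparison only)."""
    fs = fs or rec.sampling_rate
    foot = "left" if rec.placement.startswith("left") else "right"
    return detect_strides(np.abs(rec.acc[2]), fs, expected_sf=expected_sf, foot=foot)


def temporal_variables(events: GaitEventSeries) -> pd.DataFrame:
    """Per-stride stride frequency and duty factor.

    Returns a frame with columns (time, sf, df): time is the stride
    midpoint, sf = 1/interval in Hz, df = contact/interval. Strides
    whose duty factor falls outside (0, 1) are dropped; their count is
    recorded in ``frame.attrs['n_dropped']``.
    """
    fs, to = events.foot_strikes, events.toe_offs
    if len(fs) < 2:
        raise ValueError("need at least two foot strikes")
    n = min(len(fs) - 1, len(to))
    intervals = np.diff(fs)[:n]
    contact = to[:n] - fs[:n]
    sf = 1.0 / intervals
    df = contact / intervals
    mid = fs[:n] + intervals / 2.0
    ok = (df > 0) & (df < 1)
    frame = pd.DataFrame({"time": mid[ok], "sf": sf[ok], "df": df[ok]})
    frame.attrs["n_dropped"] = int(np.sum(~ok))
    frame.attrs["foot"] = events.foot
    return frame


def window_grid(duration: float, window: float = 2.0, step: float = 1.0) -> np.ndarray:
    """Start times of the half-open rolling windows [t, t+window)."""
    n = int(np.floor((duration - window) / step)) + 1
    return np.arange(max(n, 0)) * step


def windowed_average(
    left: pd.DataFrame,
    right: pd.DataFrame,
    duration: float,
    window: float = 2.0,
    step: float = 1.0,
) -> List[WindowEstimate]:
    """Average per-stride values onto the rolling window grid.

    A stride belongs to window [t, t+window) when its midpoint falls in
    it; windows without a full stride for a foot carry NaN for that
    foot's values (flagged missing, excluded from training downstream).
    """
    starts = window_grid(duration, window, step)
    out: List[WindowEstimate] = []

    def _means(frame: pd.DataFrame, t0: float) -> Tuple[float, float]:
        m = (frame["time"].to_numpy() >= t0) & (frame["time"].to_numpy() < t0 + window)
        if not np.any(m):
            return np.nan, np.nan
        return float(frame["sf"].to_numpy()[m].mean()), float(frame["df"].to_numpy()[m].mean())

    for t0 in starts:
        sf_l, df_l = _means(left, t0)
        sf_r, df_r = _means(right, t0)
        out.append(
            WindowEstimate(
                window_start=float(t0),
                window_length=window,
                sf_left=sf_l,
                sf_right=sf_r,
                df_left=df_l,
                df_right=df_r,
            )
        )
    return out
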