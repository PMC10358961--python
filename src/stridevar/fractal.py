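"""Detrended fluctuation analysis and Higuchi's fractal dimension.

Both estimators operate on a one-dimensional series such as the
stride-by-stride stride-frequency sequence of one foot. DFA returns
the long-range scaling exponent alpha (0.5 for uncorrelated noise,
1 for 1/f noise); Higuchi's method returns the fractal dimension of
the series graph (2 for maximally irregular, 1 for smooth curves).
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import DegenerateInputError, StrideSeries, VariabilityIndices

__all__ = [
    "default_dfa_scales",
    "dfa_alpha",
    "higuchi_d",
    "variability_from_stride_frequency",
]

#: lower end of the default DFA scale range, in samples (strides)
MIN_SCALE = 16
#: upper end of the default scale range as a fraction of the series length
MAX_SCALE_FRACTION = 1.0 / 9.0
#: number of log-spaced scales requested by default
N_SCALES = 12
#: default Higuchi maximum down-sampling factor
K_MAX = 10


def _as_series(x) -> np.ndarray:
    if isinstance(x, StrideSeries):
        x = x.stride_frequencies
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def default_dfa_scales(
    n: int,
    min_scale: int = MIN_SCALE,
    max_fraction: float = MAX_SCALE_FRACTION,
    n_scales: int = N_SCALES,
) -> np.ndarray:
    """Log-spaced integer window sizes emphasising the long-range regime.

    Scales run from ``min_scale`` to ``n * max_fraction``; duplicates
    after rounding are dropped, so fewer than ``n_scales`` distinct
    values may be returned for short series.
    """
    max_scale = int(n * max_fraction)
    if max_scale <= min_scale:
        raise ValueError(f"series too short for DFA: n={n}")
    scales = np.unique(
        np.round(np.geomspace(min_scale, max_scale, n_scales)).astype(int)
    )
    return scales


def dfa_alpha(
    series,
    scales: Optional[Sequence[int]] = None,
    detrend_order: int = 1,
) -> VariabilityIndices:
    """Detrended fluctuation analysis scaling exponent.

    The series is integrated into the profile Y(t) = sum (x_i - mean),
    split into non-overlapping windows of each size n, detrended with a
    polynomial of order ``detrend_order`` per window, and the RMS of
    the pooled residuals F(n) is regressed on n in log-log space. The
    slope is alpha.
    """
    x = _as_series(series)
    n = len(x)
    if n < 64:
        raise ValueError(f"need at least 64 points for DFA, got {n}")
    if np.ptp(x) == 0 or x.std() == 0:
        raise DegenerateInputError("constant series has no fluctuation to analyse")
    if scales is None:
        scales = default_dfa_scales(n)
    scales = np.unique(np.asarray(scales, dtype=int))
    if scales.min() < detrend_order + 2:
        raise ValueError("smallest scale must exceed detrend_order + 1")
    if scales.max() > n:
        raise ValueError("largest scale exceeds series length")
    if len(scales) < 2:
        raise ValueError("need at least two scales to fit a slope")

    profile = np.cumsum(x - x.mean())
    fluct = np.empty(len(scales))
    for i, s in enumerate(scales):
        n_win = n // s
        segs = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        # batched polynomial detrend via one least-squares solve
        design = np.vander(t, detrend_order + 1)
        coef, *_ = np.linalg.lstsq(design, segs.T, rcond=None)
        resid = segs.T - design @ coef
        fluct[i] = np.sqrt(np.mean(resid**2))

    log_n, log_f = np.log(scales), np.log(fluct)
    slope, intercept = np.polyfit(log_n, log_f, 1)
    pred = slope * log_n + intercept
    ss_res = np.sum((log_f - pred) ** 2)
    ss_tot = np.sum((log_f - log_f.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return VariabilityIndices(
        dfa_alpha=float(slope), n_points=n, dfa_scales=scales, fit_r2=float(r2)
    )


def higuchi_d(series, k_max: int = K_MAX) -> VariabilityIndices:
    """Higuchi's fractal dimension of the series graph.

    For each down-sampling factor k and offset m, the normalized curve
    length L_m(k) = (N-1) / (floor((N-m)/k) * k^2) * sum |x_{m+ik} -
    x_{m+(i-1)k}| is averaged over offsets; D is minus the slope of
    log L(k) against log k.
    """
    x = _as_series(series)
    n = len(x)
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    if n < 10 * k_max:
        raise ValueError(f"need at least {10 * k_max} points for k_max={k_max}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no curve length")

    lengths = np.empty(k_max - 1)
    ks = np.arange(2, k_max + 1)
    for j, k in enumerate(ks):
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            n_int = len(idx) - 1
            if n_int < 1:
                continue
            lm = np.abs(np.diff(x[idx])).sum() * (n - 1) / (n_int * k * k)
            lk += lm
        lengths[j] = lk / k
    slope, _ = np.polyfit(np.log(ks), np.log(lengths), 1)
    d = float(-slope)
    return VariabilityIndices(higuchi_d=d, n_points=n, k_max=k_max)


def variability_from_stride_frequency(
    sf_series,
    scales: Optional[Sequence[int]] = None,
    detrend_order: int = 1,
    k_max: int = K_MAX,
    analysis_seconds: Optional[float] = None,
    mean_sf: Optional[float] = None,
) -> VariabilityIndices:
    """Both variability indices from one stride-frequency sequence.

    When ``analysis_seconds`` is given together with ``mean_sf`` (or a
    StrideSeries input carrying its own timing), the sequence is first
    truncated to the strides falling inside the leading analysis
    window, supporting duration-sensitivity runs (2/4/6/8/10 min).
    """
    if isinstance(sf_series, StrideSeries) and analysis_seconds is not None:
        elapsed = sf_series.start_times - sf_series.start_times[0]
        sf = sf_series.stride_frequencies[elapsed < analysis_seconds]
    else:
        sf = _as_series(sf_series)
        if analysis_seconds is not None:
            rate = mean_sf if mean_sf is not None else float(np.mean(sf))
            n_keep = int(round(analysis_seconds * rate))
            sf = sf[: max(n_keep, 0)]

    d = dfa_alpha(sf, scales=scales, detrend_order=detrend_order)
    h = higuchi_d(sf, k_max=k_max)
    return VariabilityIndices(
        dfa_alpha=d.dfa_alpha,
        higuchi_d=h.higuchi_d,
        n_points=len(sf),
        dfa_scales=d.dfa_scales,
        k_max=k_max,
        fit_r2=d.fit_r2,
        analysis_seconds=analysis_seconds,
    )
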