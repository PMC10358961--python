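"""Temporal features of 120-second thorax-IMU windows.

Each of the six channels of a 120-s window is summarised by 23
features: nine scalar descriptors (shape, fractal, spectral), the
autocorrelation at lags 1..10, and the relative energies of the four
detail bands of a 4-level discrete wavelet decomposition. The
resulting 6 x 23 matrix is the input of the long-window DFA-alpha
estimator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pywt
from scipy.signal import periodogram
from scipy.stats import kurtosis, skew

from .fractal import dfa_alpha, higuchi_d
from .types import DegenerateInputError, IMURecording

__all__ = [
    "FEATURE_NAMES",
    "FeatureMatrix",
    "extract_channel_features",
    "extract_window_features",
    "rolling_feature_windows",
    "WINDOW_SECONDS",
    "STEP_SECONDS",
]

WINDOW_SECONDS = 120.0
STEP_SECONDS = 20.0
HIGUCHI_KMAX = 10
#: gait-cycle lags (in cycles) of the ten autocorrelation features;
#: geometric spacing traces the stride-to-stride decoherence curve,
#: whose growth with lag reflects the long-range correlation of the
#: stride-interval process (cumulative phase variance ~ k^(2H))
ACF_CYCLE_LAGS = (1, 2, 3, 4, 6, 9, 13, 19, 28, 42)
WAVELET = "db4"
WAVELET_LEVEL = 4
CHANNEL_NAMES = ("a_x", "a_y", "a_z", "w_x", "w_y", "w_z")

#: fixed feature registry; order is stable across runs and releases
FEATURE_NAMES: List[str] = (
    [
        "skewness",
        "kurtosis",
        "higuchi_d",
        "dfa_alpha",
        "std",
        "mean",
        "spectral_centroid",
        "spectral_entropy",
        "peak_frequency",
    ]
    + [f"acf_cycle{k}" for k in ACF_CYCLE_LAGS]
    + [f"wavelet_d{j}_energy" for j in range(1, WAVELET_LEVEL + 1)]
)
assert len(FEATURE_NAMES) == 23


@dataclass
class FeatureMatrix:
    """6 channels x 23 features for one analysis window."""

    values: np.ndarray
    window_start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6, 23):
            raise ValueError(f"feature matrix must be 6x23, got {self.values.shape}")

    def flat(self) -> np.ndarray:
        return self.values.ravel()


#: plausible band for the dominant gait line, Hz
CYCLE_BAND = (0.5, 5.0)


def dominant_cycle_period(x: np.ndarray, fs: float) -> float:
    """Period (s) of the dominant spectral line in the gait band."""
    xc = x - x.mean()
    freqs = np.fft.rfftfreq(len(xc), 1.0 / fs)
    power = np.abs(np.fft.rfft(xc)) ** 2
    band = (freqs >= CYCLE_BAND[0]) & (freqs <= CYCLE_BAND[1])
    return float(1.0 / freqs[band][np.argmax(power[band])])


def _autocorrelations(x: np.ndarray, fs: float) -> np.ndarray:
    """Autocorrelation at geometric gait-cycle lags (ACF_CYCLE_LAGS).

    Lags are multiples of the dominant cycle period rather than raw
    samples: at 208 Hz a 10-sample lag spans 48 ms and sees only
    waveform smoothness, whereas cycle-lagged autocorrelation measures
    stride-to-stride coherence. Geometric spacing out to 42 cycles
    traces how coherence decays with lag — the long-range structure
    the 120-s variability estimator needs.
    """
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return np.zeros(len(ACF_CYCLE_LAGS))
    period = dominant_cycle_period(x, fs)
    n = len(xc)
    # full autocorrelation via FFT (zero-padded, biased normalisation)
    ac = np.fft.irfft(np.abs(np.fft.rfft(xc, 2 * n)) ** 2)[:n]
    ac /= ac[0]
    lags = np.minimum(
        (np.asarray(ACF_CYCLE_LAGS) * period * fs).round().astype(int), n - 1
    )
    return ac[lags]


def _wavelet_energies(x: np.ndarray) -> np.ndarray:
    coeffs = pywt.wavedec(x - x.mean(), WAVELET, level=WAVELET_LEVEL)
    energies = np.array([np.sum(c**2) for c in coeffs])  # [A4, D4, D3, D2, D1]
    total = energies.sum()
    if total == 0:
        return np.zeros(WAVELET_LEVEL)
    rel = energies / total
    return rel[1:][::-1]  # D1, D2, D3, D4


def extract_channel_features(signal: np.ndarray, fs: float) -> np.ndarray:
    """The 23-feature vector of one 120-s channel, in registry order.

    A constant channel gets zero shape/spectral/autocorrelation
    features and NaN fractal features; the window-level extractor
    treats those NaNs as an error rather than passing them on.
    """
    x = np.asarray(signal, dtype=float).ravel()
    expected = WINDOW_SECONDS * fs
    if abs(len(x) - expected) > 1:
        raise ValueError(f"expected {expected:.0f} samples (120 s at {fs} Hz), got {len(x)}")

    if np.ptp(x) == 0:
        out = np.zeros(23)
        out[2] = out[3] = np.nan  # fractal features are undefined, flag them
        out[5] = x[0] if len(x) else 0.0
        return out

    freqs, power = periodogram(x, fs=fs, detrend="constant")
    freqs, power = freqs[1:], power[1:]  # exclude DC
    psum = power.sum()
    p = power / psum
    centroid = float(np.sum(freqs * p))
    entropy = float(-np.sum(p[p > 0] * np.log(p[p > 0])) / np.log(len(p)))
    peak_freq = float(freqs[np.argmax(power)])

    values = np.concatenate(
        [
            [
                float(skew(x)),
                float(kurtosis(x)),  # excess kurtosis
                higuchi_d(x, k_max=HIGUCHI_KMAX).higuchi_d,
                dfa_alpha(x).dfa_alpha,
                float(x.std()),
                float(x.mean()),
                centroid,
                entropy,
                peak_freq,
            ],
            _autocorrelations(x, fs),
            _wavelet_energies(x),
        ]
    )
    return values


def extract_window_features(
    rec: IMURecording, start: float = 0.0, fs: Optional[float] = None
) -> FeatureMatrix:
    """Feature matrix of the 120-s thorax segment starting at ``start``."""
    if rec.placement != "thorax":
        raise ValueError("window features are defined on the thorax recording")
    fs = fs or rec.sampling_rate
    i0 = int(round((start - rec.start_time) * fs))
    i1 = i0 + int(round(WINDOW_SECONDS * fs))
    if i0 < 0 or i1 > rec.n_samples:
        raise ValueError("window extends beyond the recording")
    chans = rec.channels()[:, i0:i1]
    values = np.vstack([extract_channel_features(chans[c], fs) for c in range(6)])
    if not np.all(np.isfinite(values)):
        bad = [CHANNEL_NAMES[i] for i in np.where(~np.isfinite(values).all(axis=1))[0]]
        raise DegenerateInputError(f"non-finite features in channels {bad}")
    return FeatureMatrix(values=values, window_start=start)


def rolling_feature_windows(
    rec: IMURecording,
    window: float = WINDOW_SECONDS,
    step: float = STEP_SECONDS,
) -> List[FeatureMatrix]:
    """Feature matrices over the rolling 120-s grid stepped by 20 s."""
    n_win = int(np.floor((rec.duration - window) / step)) + 1
    if n_win < 1:
        raise ValueError("recording shorter than one analysis window")
    return [
        extract_window_features(rec, start=rec.start_time + k * step)
        for k in range(n_win)
    ]
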