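"""Long-range-correlated noise generators.

Fractional Gaussian noise (fGn) is synthesized by circulant embedding
(Davies-Harte): the target autocovariance is embedded in a circulant
matrix whose eigenvalues are obtained by FFT, giving a sample with the
exact finite-sample covariance of fGn, not an approximation. 1/f
("pink") noise, the H=1 boundary that fGn cannot reach, is synthesized
spectrally by shaping white Gaussian Fourier coefficients with a
1/sqrt(f) amplitude envelope.
"""
from __future__ import annotations

import numpy as np


def fgn_autocovariance(hurst: float, lags: np.ndarray | int) -> np.ndarray:
    """Autocovariance of unit-variance fGn: rho(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2."""
    k = np.abs(np.atleast_1d(np.asarray(lags, dtype=float)))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)


def fractional_gaussian_noise(
    n: int, hurst: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact sample of unit-variance fGn of length ``n`` with Hurst ``hurst``.

    Uses circulant embedding of the covariance; the embedding size is
    doubled until all circulant eigenvalues are non-negative (for fGn
    the minimal embedding is already valid in practice, the loop is a
    guard).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < hurst < 1.0):
        raise ValueError("hurst must lie in (0, 1) for exact fGn synthesis")
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal(n)

    m = 2
    while m < 2 * (n - 1):
        m *= 2
    for _ in range(12):
        # first row of the circulant: gamma(0..m/2) then mirrored back
        half = np.arange(m // 2 + 1)
        row = np.concatenate(
            [fgn_autocovariance(hurst, half), fgn_autocovariance(hurst, half[-2:0:-1])]
        )
        eigs = np.fft.fft(row).real
        if eigs.min() >= -1e-10 * eigs.max():
            eigs = np.clip(eigs, 0.0, None)
            break
        m *= 2
    else:  # pragma: no cover - never reached for H in (0,1)
        raise RuntimeError("circulant embedding failed to become non-negative")

    # Hermitian-symmetric Gaussian weights so the transform is real.
    w = np.zeros(m, dtype=complex)
    u = rng.standard_normal(m // 2 + 1)
    v = rng.standard_normal(m // 2 + 1)
    w[0] = np.sqrt(eigs[0] / m) * u[0]
    w[m // 2] = np.sqrt(eigs[m // 2] / m) * u[m // 2]
    k = np.arange(1, m // 2)
    w[k] = np.sqrt(eigs[k] / (2.0 * m)) * (u[k] + 1j * v[k])
    w[m - k] = np.conj(w[k])
    z = np.fft.fft(w).real
    return z[:n]


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-spectrum Gaussian noise of length ``n``.

    Fourier amplitudes follow f^(-1/2) so power follows 1/f; the DFA
    scaling exponent of such a series is 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    coeff = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real
    x = np.fft.irfft(coeff, n=n)
    sd = x.std()
    if sd == 0:  # pragma: no cover
        raise RuntimeError("degenerate spectral synthesis")
    return x / sd
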