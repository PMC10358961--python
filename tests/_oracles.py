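"""Independent, deliberately naive reference implementations.

These exist to cross-check the package's estimators through a second
code path: explicit Python loops, np.polyfit per window, no shared
helpers with src/. They trade speed for obviousness.
"""
from __future__ import annotations

import numpy as np


def dfa_reference(x: np.ndarray, scales, order: int = 1) -> float:
    """Loop-based DFA: slope of log F(n) vs log n, pooled residual RMS."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - np.mean(x))
    log_n, log_f = [], []
    for s in scales:
        residues = []
        n_win = len(profile) // s
        for w in range(n_win):
            seg = profile[w * s : (w + 1) * s]
            t = np.arange(s)
            coeffs = np.polyfit(t, seg, order)
            fit = np.polyval(coeffs, t)
            residues.extend((seg - fit) ** 2)
        log_n.append(np.log(s))
        log_f.append(np.log(np.sqrt(np.mean(residues))))
    return float(np.polyfit(log_n, log_f, 1)[0])


def higuchi_reference(x: np.ndarray, k_max: int) -> float:
    """Loop-based Higuchi dimension: -slope of log L(k) vs log k."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    log_k, log_l = [], []
    for k in range(2, k_max + 1):
        lengths = []
        for m in range(k):
            total = 0.0
            n_int = (n - 1 - m) // k
            if n_int < 1:
                continue
            for i in range(1, n_int + 1):
                total += abs(x[m + i * k] - x[m + (i - 1) * k])
            lengths.append(total * (n - 1) / (n_int * k * k))
        log_k.append(np.log(k))
        log_l.append(np.log(np.mean(lengths)))
    return float(-np.polyfit(log_k, log_l, 1)[0])


def autocorr_reference(x: np.ndarray, k: int) -> float:
    """Brute-force lag-k autocorrelation, mean-subtracted, biased norm."""
    x = np.asarray(x, dtype=float)
    xb = np.mean(x)
    num = sum((x[t] - xb) * (x[t + k] - xb) for t in range(len(x) - k))
    den = sum((x[t] - xb) ** 2 for t in range(len(x)))
    return num / den


def kruskal_reference(groups) -> float:
    """Hand-computed Kruskal-Wallis H with tie correction."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(all_vals)
    order = np.argsort(all_vals)
    ranks = np.empty(n)
    i = 0
    svals = all_vals[order]
    while i < n:
        j = i
        while j + 1 < n and svals[j + 1] == svals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos : pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie
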