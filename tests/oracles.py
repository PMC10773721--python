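"""Independent brute-force oracles for the image encodings.

Deliberately written as naive scalar double loops, sharing no code with the
package implementation, so agreement is a genuine cross-check.
"""

import math

import numpy as np


def gasf_bruteforce(series):
    theta = [math.acos(min(1.0, max(0.0, v))) for v in series]
    n = len(theta)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.cos(theta[i] + theta[j])
    return out


def gadf_bruteforce(series):
    theta = [math.acos(min(1.0, max(0.0, v))) for v in series]
    n = len(theta)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = math.sin(theta[i] - theta[j])
    return out


def _bin_of(value, q):
    # uniform bins over [0, 1], right-closed at 1
    b = int(value * q)
    return min(b, q - 1)


def mtf_bruteforce(series, q):
    n = len(series)
    bins = [_bin_of(v, q) for v in series]
    counts = [[0.0] * q for _ in range(q)]
    for t in range(n - 1):
        counts[bins[t]][bins[t + 1]] += 1.0
    w = [[0.0] * q for _ in range(q)]
    for i in range(q):
        total = sum(counts[i])
        if total > 0:
            for j in range(q):
                w[i][j] = counts[i][j] / total
    out = np.empty((n, n))
    for k in range(n):
        for m in range(n):
            out[k, m] = w[bins[k]][bins[m]]
    return out


def rp_bruteforce(series, epsilon):
    n = len(series)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = 1.0 if abs(series[i] - series[j]) < epsilon else 0.0
    return out
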