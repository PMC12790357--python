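"""Independent brute-force reference implementations used only by tests.

These deliberately use explicit Python loops and textbook formulas, sharing
no code with the package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def jaccard_oracle(x, ya, yb, eps=0.0):
    """Geometric Jaccard by explicit per-point loops and trapezoid areas."""
    n = len(x)
    lower = [0.0] * n
    upper = [0.0] * n
    for i in range(n):
        if abs(ya[i] - yb[i]) <= eps:
            m = (ya[i] + yb[i]) / 2.0
            lower[i] = m
            upper[i] = m
        else:
            lower[i] = min(ya[i], yb[i])
            upper[i] = max(ya[i], yb[i])
    inter = 0.0
    union = 0.0
    for i in range(n - 1):
        dx = x[i + 1] - x[i]
        inter += 0.5 * (lower[i] + lower[i + 1]) * dx
        union += 0.5 * (upper[i] + upper[i + 1]) * dx
    if union == 0.0:
        return 1.0, inter, union
    return inter / union, inter, union


def xcorr_oracle(f, g, max_lag=None):
    """O(n^2) double-loop normalized max cross-correlation, lags 0..max_lag."""
    f = [complex(v) for v in f]
    g = [complex(v) for v in g]
    n = max(len(f), len(g))
    f = f + [0j] * (n - len(f))
    g = g + [0j] * (n - len(g))
    if max_lag is None:
        max_lag = n - 1
    ef = sum(abs(v) ** 2 for v in f)
    eg = sum(abs(v) ** 2 for v in g)
    best_val = None
    best_lag = 0
    for lag in range(0, max_lag + 1):
        c = 0j
        for t in range(n - lag):
            c += f[t].conjugate() * g[t + lag]
        score = c.real
        if best_val is None or score > best_val:
            best_val = score
            best_lag = lag
    return best_val / np.sqrt(ef * eg), best_lag


def plateau_oracle(values, window, threshold):
    """First index whose trailing-window OLS slope magnitude is below threshold."""
    n = len(values)
    for i in range(window - 1, n):
        x = np.arange(i - window + 1, i + 1, dtype=float)
        y = np.asarray(values[i - window + 1 : i + 1], dtype=float)
        slope = np.polyfit(x, y, 1)[0]
        if abs(slope) < threshold:
            return i
    return None
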