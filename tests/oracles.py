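"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — explicit z-normalization, O(n^2 L)
loops, direct crossing counts — and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def znorm(w: np.ndarray) -> np.ndarray:
    s = w.std()
    if s == 0:
        return np.zeros_like(w)
    return (w - w.mean()) / s


def naive_distance_profile(query: np.ndarray, series: np.ndarray) -> np.ndarray:
    L = len(query)
    zq = znorm(np.asarray(query, float))
    out = np.empty(len(series) - L + 1)
    for j in range(out.size):
        out[j] = np.linalg.norm(zq - znorm(series[j : j + L]))
    return out


def naive_matrix_profile(
    series: np.ndarray,
    L: int,
    excl: int,
    direction: str = "both",
    tc: int | None = None,
):
    """Exhaustive all-pairs one-nearest-neighbor scan (smallest index on ties)."""
    x = np.asarray(series, float)
    m = x.size - L + 1
    Z = [znorm(x[i : i + L]) for i in range(m)]
    values = np.full(m, np.inf)
    index = np.full(m, -1, dtype=np.int64)
    for i in range(m):
        for j in range(m):
            if abs(i - j) <= excl:
                continue
            if tc is not None and abs(i - j) > tc:
                continue
            if direction == "left" and j >= i:
                continue
            d = float(np.linalg.norm(Z[i] - Z[j]))
            if d < values[i] - 1e-12:  # strict improvement: first index wins ties
                values[i] = d
                index[i] = j
    return values, index


def naive_crossing_counts(mp_index, n: int) -> np.ndarray:
    """Direct per-position arc-crossing count under min(i,j) <= x < max(i,j)."""
    counts = np.zeros(n, dtype=np.int64)
    for i, j in enumerate(np.asarray(mp_index, dtype=np.int64)):
        if j < 0:
            continue
        lo, hi = (i, j) if i < j else (j, i)
        counts[lo:hi] += 1
    return counts


def naive_score(predicted, truth, n: int) -> float:
    total = 0
    for p in predicted:
        total += min(abs(int(p) - int(t)) for t in truth)
    return total / (len(predicted) * n)
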