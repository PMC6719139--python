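"""Naive reference implementations used to cross-check the fast paths.

Everything here is written as plain per-index loops — O(n*w) for the
window transfer functions, exhaustive recursion for beat matching — and is
deliberately independent of the vectorized implementations under test.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks


def naive_extrema(x):
    """Strict local extrema; plateaus count once at their first sample."""
    n = len(x)
    is_max = np.zeros(n, dtype=bool)
    is_min = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        if x[i] == x[i - 1]:
            continue  # plateau continuation
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 >= n:
            continue  # plateau runs to the array end
        if x[i] > x[i - 1] and x[i] > x[j + 1]:
            is_max[i] = True
        if x[i] < x[i - 1] and x[i] < x[j + 1]:
            is_min[i] = True
    return is_max, is_min


def naive_varwin_hr(x, fs, span_ms):
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(round(span_ms / 1000.0 * fs))
    h = w // 2
    is_max, is_min = naive_extrema(x)
    out = np.zeros(n)
    for i in range(n):
        lo, hi = max(0, i - h), min(n - 1, i + h)
        glo, ghi = max(0, i - (h - 1)), min(n - 1, i + (h - 1))
        gate = is_max[glo : ghi + 1].any() and is_min[glo : ghi + 1].any()
        if gate:
            seg = x[lo : hi + 1]
            out[i] = seg.max() - seg.min()
    return out


def naive_varwin_beat(x, fs, span_ms, suppress_ms=None, prom_frac=0.6):
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(round(span_ms / 1000.0 * fs))
    if suppress_ms is None:
        suppress_ms = span_ms
    is_max, is_min = naive_extrema(x)
    out = np.zeros(n)
    for i in range(n):
        hi = min(n - 1, i + w - 1)
        ghi = min(n - 1, i + w - 2)
        gate = is_max[i : ghi + 1].any() and is_min[i : ghi + 1].any()
        if gate:
            out[i] = x[i] - x[i : hi + 1].min()
    span = x.max() - x.min() if n else 0.0
    if span > 0:
        minima, _ = find_peaks(-x, prominence=prom_frac * span)
        supp = int(round(suppress_ms / 1000.0 * fs))
        for m in minima:
            out[m + 1 : m + 1 + supp] = 0.0
    return out


def brute_force_match(det, ref, tol):
    """Exhaustive optimal one-to-one matching: max pairs, then min total
    offset.  Returns (tp, total_cost)."""
    det = list(det)
    ref = list(ref)

    best = (0, 0.0)

    def recurse(i, used, tp, cost):
        nonlocal best
        if i == len(det):
            if (tp, -cost) > (best[0], -best[1]):
                best = (tp, cost)
            return
        if tp + (len(det) - i) < best[0]:
            return
        recurse(i + 1, used, tp, cost)  # leave detection i unmatched
        for j, r in enumerate(ref):
            if j not in used and abs(det[i] - r) <= tol:
                recurse(i + 1, used | {j}, tp + 1, cost + abs(det[i] - r))

    recurse(0, frozenset(), 0, 0.0)
    return best
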