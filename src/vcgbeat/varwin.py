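"""VarWin amplitude-variation transfer functions.

VarWin is an irreversible transfer function that amplifies short-span
oscillations — the signature of the first heart sound (S1) in sternal
vibration signals.  A peak in the output marks the joint occurrence of a
local maximum and a local minimum within the analysis span, which is what the
aortic-opening (AO) / isovolumetric-contraction (IC) complex produces.

Two variants are provided:

``varwin_hr``
    Centered window.  At index ``i`` the output is the windowed range
    ``max - min`` multiplied by a binary gate that requires at least one
    local maximum AND one local minimum strictly inside the window.  Smooth
    trends (constants, monotone ramps) map to zero, so the autocorrelation of
    the output carries much cleaner beat harmonics than the raw waveform.

``varwin_beat``
    Strictly forward-looking window, used for beat localization.  The output
    at ``i`` is the *anchored* range ``x[i] - min(x[i .. i+span])`` gated the
    same way, so the response peaks sharply at the AO maximum itself instead
    of forming a plateau ahead of it.  Output falling in a suppression span
    directly after a prominent local minimum is zeroed, which mutes features
    that ride on the recovery limb of a preceding trough (rapid-ejection and
    aortic-closing lookalikes).

Both variants are scale-covariant (``varwin(c*x) = c*varwin(x)`` for c > 0)
and invariant to constant offsets.  The vectorized implementation is required
to match the naive O(n*w) sliding-window definition bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

from .errors import ParameterError
from .preprocess import UniformSignal

#: Default analysis span: approximately the S1 complex duration.
DEFAULT_SPAN_MS = 250.0

#: Minimum prominence of a raw-signal minimum that triggers suppression,
#: as a fraction of the signal's full range.
DEFAULT_SUPPRESS_PROM_FRAC = 0.6


@dataclass
class EnhancedSignal:
    """Non-negative VarWin output aligned sample-for-sample with its source."""

    values: np.ndarray
    fs: float
    t0: float
    variant: str
    span_ms: float
    channel_id: str = ""

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


def local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of strict local maxima and minima.

    Plateaus count once, attributed to their first sample.  Array endpoints
    are never extrema.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    is_max = np.zeros(n, dtype=bool)
    is_min = np.zeros(n, dtype=bool)
    if n < 3:
        return is_max, is_min
    change = np.flatnonzero(np.diff(x) != 0.0)
    if change.size < 2:
        return is_max, is_min
    # run start indices: 0 plus the sample after each value change
    starts = np.concatenate(([0], change + 1))
    vals = x[starts]
    rising = vals[1:-1] > vals[:-2]
    above = vals[1:-1] > vals[2:]
    interior = starts[1:-1]
    is_max[interior[rising & above]] = True
    is_min[interior[(~rising) & (~above)]] = True
    return is_max, is_min


def _win_max(x: np.ndarray, left: int, right: int) -> np.ndarray:
    """Max over the index window ``[i-left, i+right]`` clipped to bounds."""
    if left + right == 0:
        return x.copy()
    xp = np.pad(x, (left, right), constant_values=-np.inf)
    return sliding_window_view(xp, left + right + 1).max(axis=1)


def _win_min(x: np.ndarray, left: int, right: int) -> np.ndarray:
    if left + right == 0:
        return x.copy()
    xp = np.pad(x, (left, right), constant_values=np.inf)
    return sliding_window_view(xp, left + right + 1).min(axis=1)


def _win_any(mask: np.ndarray, left: int, right: int) -> np.ndarray:
    """True where the window ``[i-left, i+right]`` contains a True sample."""
    if left < 0 or right < 0 or left + right < 0:
        return np.zeros(mask.size, dtype=bool)
    mp = np.pad(mask, (max(left, 0), max(right, 0)), constant_values=False)
    return sliding_window_view(mp, left + right + 1).any(axis=1)


def _span_samples(span_ms: float, fs: float) -> int:
    w = int(round(span_ms / 1000.0 * fs))
    if w < 3:
        raise ParameterError(f"span {span_ms} ms is shorter than 3 samples at {fs} Hz")
    return w


def varwin_hr(sig: UniformSignal, span_ms: float = DEFAULT_SPAN_MS) -> EnhancedSignal:
    """Centered-window VarWin for averaged heart-rate estimation.

    ``V[i] = (max - min over [i-h, i+h]) * G[i]`` with ``h = w // 2`` and
    ``G[i] = 1`` iff at least one local maximum and one local minimum lie
    strictly inside the window (indices ``(i-h, i+h)``), both clipped at the
    array bounds.
    """
    w = _span_samples(span_ms, sig.fs)
    if sig.values.size <= w:
        raise ParameterError("signal shorter than the analysis span")
    x = sig.values
    h = w // 2
    rng = _win_max(x, h, h) - _win_min(x, h, h)
    is_max, is_min = local_extrema(x)
    gate = _win_any(is_max, h - 1, h - 1) & _win_any(is_min, h - 1, h - 1)
    return EnhancedSignal(values=rng * gate, fs=sig.fs, t0=sig.t0,
                          variant="hr", span_ms=span_ms, channel_id=sig.channel_id)


def suppression_mask(
    x: np.ndarray,
    fs: float,
    suppress_ms: float,
    prom_frac: float = DEFAULT_SUPPRESS_PROM_FRAC,
) -> np.ndarray:
    """True where output must be zeroed: within ``suppress_ms`` after a
    prominent local minimum of ``x``.

    A minimum qualifies when its prominence reaches ``prom_frac`` of the
    signal's full range, keeping the operator scale-covariant and immune to
    incidental noise troughs.
    """
    x = np.asarray(x, dtype=float)
    span = float(x.max() - x.min()) if x.size else 0.0
    mask = np.zeros(x.size, dtype=bool)
    if span <= 0:
        return mask
    minima, _ = find_peaks(-x, prominence=prom_frac * span)
    supp = int(round(suppress_ms / 1000.0 * fs))
    for m in minima:
        mask[m + 1 : m + 1 + supp] = True
    return mask


def varwin_beat(
    sig: UniformSignal,
    span_ms: float = DEFAULT_SPAN_MS,
    suppress_ms: float | None = None,
    suppress_prom_frac: float = DEFAULT_SUPPRESS_PROM_FRAC,
) -> EnhancedSignal:
    """Forward-looking VarWin for AO beat localization.

    ``V[i] = (x[i] - min(x[i .. i+w-1])) * G[i] * S[i]`` where the gate ``G``
    requires a local maximum and a local minimum among indices
    ``[i, i+w-2]`` (the current point may itself be the maximum) and ``S``
    zeroes a suppression span directly after each prominent raw-signal
    minimum.  ``suppress_ms`` defaults to the analysis span.
    """
    w = _span_samples(span_ms, sig.fs)
    if sig.values.size <= w:
        raise ParameterError("signal shorter than the analysis span")
    if suppress_ms is None:
        suppress_ms = span_ms
    x = sig.values
    rng = x - _win_min(x, 0, w - 1)
    is_max, is_min = local_extrema(x)
    gate = _win_any(is_max, 0, w - 2) & _win_any(is_min, 0, w - 2)
    keep = ~suppression_mask(x, sig.fs, suppress_ms, suppress_prom_frac)
    return EnhancedSignal(values=rng * gate * keep, fs=sig.fs, t0=sig.t0,
                          variant="beat", span_ms=span_ms, channel_id=sig.channel_id)
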